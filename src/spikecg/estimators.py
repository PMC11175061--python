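"""scikit-learn style estimators wrapping the networks.

:class:`AttentionSNNClassifier` is the package's headline model — the
six-layer attention-gated spiking network trained with surrogate-gradient
BPTT.  :class:`ConvNetClassifier` is the twelve-layer conventional baseline.
Both follow the sklearn contract (``get_params``/``set_params``, ``fit``,
``predict``, ``predict_proba``, fitted attributes with trailing
underscores), so they compose with pipelines and model selection.
:class:`WaveletDenoiser` is a stateless transformer applying wavelet
thresholding row-wise.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._nn import Adam, softmax, softmax_cross_entropy
from .attention import AttentionConfig
from .models import build_ann12, build_snn6
from .preprocess import DenoiseConfig, denoise
from .spiking import LIFParams

__all__ = ["AttentionSNNClassifier", "ConvNetClassifier", "WaveletDenoiser"]


def _standardize(X: np.ndarray) -> np.ndarray:
    """Per-segment z-scoring; constant rows map to zero."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


class _TrainerMixin:
    """Shared seeded mini-batch Adam/cross-entropy loop."""

    def _train_network(self, net, X, y_idx, sample_weight=None):
        rng = np.random.default_rng(
            self.random_state if self.random_state is not None else 0
        )
        opt = Adam(net.params(), lr=self.learning_rate)
        n = X.shape[0]
        class_w = None
        if getattr(self, "class_weight", None) == "balanced":
            counts = np.bincount(y_idx, minlength=len(self.classes_))
            class_w = n / (len(self.classes_) * np.maximum(counts, 1))
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = net.forward(X[idx])
                loss, grad = softmax_cross_entropy(logits, y_idx[idx])
                if class_w is not None:
                    w = class_w[y_idx[idx]]
                    grad = grad * w[:, None]
                    loss = float(loss * w.mean())
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                opt.zero_grad()
                net.backward(grad)
                opt.step()
                epoch_loss += loss * idx.size
                seen += idx.size
            history.append(epoch_loss / seen)
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs}: loss {history[-1]:.4f}")
        return history

    def _decision(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; expected {self.n_features_in_}"
            )
        Xs = _standardize(X) if self.normalize else X
        out = []
        for start in range(0, X.shape[0], 256):
            out.append(self.network_.forward(Xs[start : start + 256]))
        return np.vstack(out)

    def predict_proba(self, X):
        return softmax(self._decision(X))

    def predict(self, X):
        return self.classes_[np.argmax(self._decision(X), axis=1)]

    def _fit_common(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        Xs = _standardize(X) if self.normalize else X
        return Xs, y_idx


class AttentionSNNClassifier(_TrainerMixin, ClassifierMixin, BaseEstimator):
    """Six-layer attention-gated spiking classifier for beat segments.

    The input segment is pooled to ``slice_count`` time slices, gated by
    multi-head per-slice attention weights, and driven through four fully
    connected LIF layers for ``timesteps`` discrete steps; class logits are
    output-layer spike counts (or mean membrane potential).  Training is
    mini-batch Adam with cross-entropy and a surrogate spike derivative.

    Parameters mirror the published protocol where one was printed
    (epochs=200, learning_rate=1e-3, batch_size=64, timesteps=100) and
    standard defaults elsewhere.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (256, 128, 64),
        n_heads: int = 4,
        slice_count: int = 250,
        timesteps: int = 100,
        leak_lambda: float = 0.9,
        v_threshold: float = 1.0,
        readout: str = "spike_count",
        surrogate_kind: str = "arctan",
        surrogate_alpha: float = 2.0,
        epochs: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        class_weight: str | None = None,
        normalize: bool = True,
        random_state: int | None = None,
        verbose: int = 0,
    ) -> None:
        self.hidden_layer_sizes = hidden_layer_sizes
        self.n_heads = n_heads
        self.slice_count = slice_count
        self.timesteps = timesteps
        self.leak_lambda = leak_lambda
        self.v_threshold = v_threshold
        self.readout = readout
        self.surrogate_kind = surrogate_kind
        self.surrogate_alpha = surrogate_alpha
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.normalize = normalize
        self.random_state = random_state
        self.verbose = verbose

    def _build(self, input_length: int, n_classes: int):
        seed = self.random_state if self.random_state is not None else 0
        return build_snn6(
            class_count=n_classes,
            lif=LIFParams(
                leak_lambda=self.leak_lambda, v_threshold=self.v_threshold
            ),
            attn=AttentionConfig(
                n_heads=self.n_heads, slice_count=self.slice_count, seed=seed
            ),
            T=self.timesteps,
            input_length=input_length,
            hidden_sizes=tuple(self.hidden_layer_sizes),
            readout=self.readout,
            seed=seed,
            surrogate_kind=self.surrogate_kind,
            surrogate_alpha=self.surrogate_alpha,
        )

    def fit(self, X, y):
        Xs, y_idx = self._fit_common(X, y)
        self.network_ = self._build(Xs.shape[1], self.classes_.size)
        self.loss_history_ = self._train_network(self.network_, Xs, y_idx)
        return self

    @property
    def attention_weights_(self):
        """Head-averaged attention weights of the last forward pass."""
        check_is_fitted(self, "network_")
        lw = self.network_.attention.last_weights_
        return None if lw is None else lw.averaged


class ConvNetClassifier(_TrainerMixin, ClassifierMixin, BaseEstimator):
    """Twelve-layer convolutional baseline (conv/pool stack + FC classifier)."""

    def __init__(
        self,
        activation: str = "leaky_relu",
        conv_channels: tuple[int, int, int] = (8, 16, 32),
        fc_sizes: tuple[int, int, int] = (256, 128, 64),
        epochs: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        class_weight: str | None = None,
        normalize: bool = True,
        random_state: int | None = None,
        verbose: int = 0,
    ) -> None:
        self.activation = activation
        self.conv_channels = conv_channels
        self.fc_sizes = fc_sizes
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.normalize = normalize
        self.random_state = random_state
        self.verbose = verbose

    def fit(self, X, y):
        Xs, y_idx = self._fit_common(X, y)
        self.network_ = build_ann12(
            class_count=self.classes_.size,
            activation=self.activation,
            input_length=Xs.shape[1],
            conv_channels=tuple(self.conv_channels),
            fc_sizes=tuple(self.fc_sizes),
            seed=self.random_state if self.random_state is not None else 0,
        )
        self.loss_history_ = self._train_network(self.network_, Xs, y_idx)
        return self


class WaveletDenoiser(TransformerMixin, BaseEstimator):
    """Row-wise wavelet-threshold denoising as an sklearn transformer."""

    def __init__(
        self,
        wavelet_name: str = "db6",
        decomposition_level: int = 6,
        threshold_rule: str = "universal",
        threshold_mode: str = "soft",
    ) -> None:
        self.wavelet_name = wavelet_name
        self.decomposition_level = decomposition_level
        self.threshold_rule = threshold_rule
        self.threshold_mode = threshold_mode

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X, dtype=float)
        cfg = DenoiseConfig(
            wavelet_name=self.wavelet_name,
            decomposition_level=self.decomposition_level,
            threshold_rule=self.threshold_rule,
            threshold_mode=self.threshold_mode,
        )
        return np.stack([denoise(row, cfg) for row in X])
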