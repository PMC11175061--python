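"""Multi-head time-slice attention over beat segments.

The mechanism is a per-time-slice gating, not dot-product attention: a small
feature stack (two 2-channel convolutions, each followed by average pooling)
summarizes the segment; each head projects the flattened features through a
fully connected layer to one logit per time slice and a SoftMax normalizes
them to a weight vector on the probability simplex; the heads' vectors are
averaged and multiplied element-wise into the (slice-resolution) input that
feeds the spiking stack.

A segment of 501 samples is first reduced to ``slice_count`` slices
(default 250) by non-overlapping average pooling, so the attention vector
and the gated representation share one time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import AvgPool1d, Conv1d, Flatten, Layer, Linear, Param, ReLU, softmax

__all__ = [
    "AttentionConfig",
    "AttentionWeights",
    "TimeSliceAttention",
    "conv_pool_features",
    "head_weights",
    "apply_attention",
    "multi_head",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Architecture of the attention block.

    ``slice_count`` is the length of the attention-weight vector (one weight
    per time slice); ``conv_kernels`` and ``pool_sizes`` configure the two
    convolution/pooling stages; ``channels`` is the feature depth after each
    convolution.
    """

    n_heads: int = 4
    slice_count: int = 250
    conv_kernels: tuple[int, int] = (7, 5)
    pool_sizes: tuple[int, int] = (2, 2)
    channels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if self.slice_count < 1:
            raise ValueError("slice_count must be >= 1")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")


@dataclass
class AttentionWeights:
    """Per-head and head-averaged attention weights (each on the simplex)."""

    per_head: np.ndarray  # (n_heads, slice_count) or (n_heads, N, slice_count)
    averaged: np.ndarray  # (slice_count,) or (N, slice_count)


def _slice_pool_size(input_length: int, slice_count: int) -> int:
    p = input_length // slice_count
    if p < 1 or input_length // p != slice_count:
        raise ValueError(
            f"input length {input_length} cannot be pooled onto "
            f"{slice_count} time slices"
        )
    return p


class TimeSliceAttention(Layer):
    """Trainable attention block; batched input (N, input_length)."""

    def __init__(self, input_length: int, config: AttentionConfig,
                 rng: np.random.Generator | None = None) -> None:
        self.config = config
        self.input_length = input_length
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.slicer = AvgPool1d(_slice_pool_size(input_length, config.slice_count))
        k1, k2 = config.conv_kernels
        p1, p2 = config.pool_sizes
        c = config.channels
        self.conv1 = Conv1d(1, c, k1, rng)
        self.act1 = ReLU()
        self.pool1 = AvgPool1d(p1)
        self.conv2 = Conv1d(c, c, k2, rng)
        self.act2 = ReLU()
        self.pool2 = AvgPool1d(p2)
        self.flatten = Flatten()
        feat_len = c * ((config.slice_count // p1) // p2)
        self.heads = [
            Linear(feat_len, config.slice_count, rng, init_scale=np.sqrt(1.0 / feat_len))
            for _ in range(config.n_heads)
        ]
        self._cache: dict | None = None
        self.last_weights_: AttentionWeights | None = None

    # -- architecture pieces -------------------------------------------------

    def params(self) -> list[Param]:
        out = self.conv1.params() + self.conv2.params()
        for h in self.heads:
            out += h.params()
        return out

    def features(self, sliced: np.ndarray) -> np.ndarray:
        """Conv/pool feature stack on the sliced input (N, slice_count)."""
        z = sliced[:, None, :]  # (N, 1, S)
        z = self.pool1(self.act1(self.conv1(z)))
        z = self.pool2(self.act2(self.conv2(z)))
        return self.flatten(z)

    def weights(self, x: np.ndarray) -> tuple[AttentionWeights, np.ndarray]:
        """Compute attention weights for a batch; returns (weights, sliced)."""
        sliced = self.slicer(x)
        feats = self.features(sliced)
        logits = np.stack([h.forward(feats) for h in self.heads])  # (H, N, S)
        per_head = softmax(logits, axis=-1)
        averaged = per_head.mean(axis=0)
        return AttentionWeights(per_head=per_head, averaged=averaged), sliced

    # -- Layer interface -----------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        w, sliced = self.weights(x)
        self._cache = {"sliced": sliced, "per_head": w.per_head, "avg": w.averaged}
        self.last_weights_ = w
        return sliced * w.averaged

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        sliced = self._cache["sliced"]
        per_head = self._cache["per_head"]
        avg = self._cache["avg"]
        h = per_head.shape[0]

        d_sliced = grad * avg  # direct gating path
        d_avg = grad * sliced
        d_feats = None
        for i, head in enumerate(self.heads):
            w = per_head[i]
            dw = d_avg / h
            # softmax Jacobian-vector product
            dlogits = w * (dw - (dw * w).sum(axis=-1, keepdims=True))
            df = head.backward(dlogits)
            d_feats = df if d_feats is None else d_feats + df
        z = self.flatten.backward(d_feats)
        z = self.conv2.backward(self.act2.backward(self.pool2.backward(z)))
        z = self.conv1.backward(self.act1.backward(self.pool1.backward(z)))
        d_sliced = d_sliced + z[:, 0, :]
        return self.slicer.backward(d_sliced)


# -- functional surface ------------------------------------------------------


def _block(input_length: int, config: AttentionConfig) -> TimeSliceAttention:
    return TimeSliceAttention(input_length, config)


def conv_pool_features(
    segment: np.ndarray, config: AttentionConfig = AttentionConfig()
) -> np.ndarray:
    """Feature map of one segment through the 2x(conv+pool) stack."""
    x = np.atleast_2d(np.asarray(segment, dtype=float))
    block = _block(x.shape[-1], config)
    return block.features(block.slicer(x))[0]


def head_weights(
    features: np.ndarray,
    head_index: int,
    config: AttentionConfig = AttentionConfig(),
    block: TimeSliceAttention | None = None,
) -> np.ndarray:
    """One head's attention vector (nonnegative, sums to 1)."""
    if block is None:
        block = _block(config.slice_count, config)
    if head_index >= len(block.heads):
        raise IndexError(f"head_index {head_index} out of range")
    f = np.atleast_2d(np.asarray(features, dtype=float))
    return softmax(block.heads[head_index].forward_nocache(f), axis=-1)[0]


def apply_attention(segment: np.ndarray, averaged_weights: np.ndarray) -> np.ndarray:
    """Element-wise reweighting: out[t, c] = in[t, c] * w[t].

    ``segment`` may be (time,) or (time, channels); the weight vector is
    broadcast across channels.
    """
    x = np.asarray(segment, dtype=float)
    w = np.asarray(averaged_weights, dtype=float)
    if x.shape[0] != w.shape[0]:
        raise ValueError(
            f"time-axis mismatch: segment has {x.shape[0]} slices, "
            f"weights have {w.shape[0]}"
        )
    return x * (w if x.ndim == 1 else w[:, None])


def multi_head(
    segment: np.ndarray, config: AttentionConfig = AttentionConfig()
) -> tuple[AttentionWeights, np.ndarray]:
    """Full attention pass over one segment with fresh (seeded) parameters."""
    x = np.atleast_2d(np.asarray(segment, dtype=float))
    block = _block(x.shape[-1], config)
    w, sliced = block.weights(x)
    weights = AttentionWeights(per_head=w.per_head[:, 0, :], averaged=w.averaged[0])
    return weights, apply_attention(sliced[0], weights.averaged)
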