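"""Network builders and ANN-to-SNN conversion tests."""

from __future__ import annotations

import numpy as np
import pytest

from spikecg import (
    AttentionConfig,
    LIFParams,
    build_ann6,
    build_ann12,
    build_mlp,
    build_snn6,
    convert_ann_to_snn,
)
from spikecg._nn import softmax
from spikecg.models import NetworkSpec, LayerSpec, SpikingMLP

TINY_ATTN = AttentionConfig(
    n_heads=2, slice_count=10, conv_kernels=(3, 3), pool_sizes=(2, 1), seed=0
)


class TestANN12:
    def test_layer_count_is_twelve(self):
        assert build_ann12(5).spec.n_layers == 12

    def test_forward_shape_on_default_segment(self):
        net = build_ann12(5)
        X = np.random.default_rng(0).normal(size=(3, 501))
        assert net.forward(X).shape == (3, 5)

    def test_zero_final_layer_gives_uniform_probabilities(self):
        net = build_ann12(4, input_length=64)
        last = [l for l in net.net.layers if hasattr(l, "W")][-1]
        last.W.value[:] = 0.0
        last.b.value[:] = 0.0
        X = np.random.default_rng(1).normal(size=(5, 64))
        probs = softmax(net.forward(X))
        assert np.allclose(probs, 0.25)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            build_ann12(1)
        with pytest.raises(ValueError):
            build_ann12(2, activation="tanh")


class TestSNN6:
    def test_four_lif_layers_after_attention(self):
        net = build_snn6(5)
        assert net.spec.n_layers == 6
        lif_layers = [l for l in net.spec.layers if l.activation == "lif"]
        assert len(lif_layers) == 4
        assert net.spec.layers[0].kind == net.spec.layers[1].kind == "attn_conv"

    def test_single_step_spike_count_bounded_by_one(self):
        net = build_snn6(3, T=1, attn=TINY_ATTN, input_length=20,
                         hidden_sizes=(8, 6, 4), seed=1)
        X = np.random.default_rng(0).normal(size=(10, 20)) * 5
        logits = net.forward(X)
        assert np.isin(logits, (0.0, 1.0)).all()

    def test_total_spikes_nondecreasing_in_T(self):
        net = build_snn6(3, T=1, attn=TINY_ATTN, input_length=20,
                         hidden_sizes=(8, 6, 4), seed=2)
        X = np.abs(np.random.default_rng(1).normal(size=(6, 20))) * 3
        totals = []
        for T in (1, 2, 4, 8, 16):
            logits = net.forward(X, T=T)
            totals.append(logits.sum())
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    def test_forward_deterministic(self):
        net = build_snn6(2, T=5, attn=TINY_ATTN, input_length=20,
                         hidden_sizes=(8, 6, 4), seed=3)
        X = np.random.default_rng(2).normal(size=(4, 20))
        assert np.array_equal(net.forward(X), net.forward(X))

    def test_spec_rejects_mixed_activations(self):
        with pytest.raises(ValueError, match="mix"):
            NetworkSpec(
                layers=(
                    LayerSpec("fc", width=4, activation="relu"),
                    LayerSpec("fc_lif", width=2, activation="lif"),
                ),
                class_count=2,
                timesteps=1,
                readout="spike_count",
            )


class TestConversion:
    def _toy_positive_mlp(self):
        mlp = build_mlp((8, 5), seed=1)
        for lin in mlp.linears:
            lin.W.value = np.abs(lin.W.value)
            lin.b.value[:] = 0.0
        return mlp

    def test_rate_matches_activation_within_10pct(self):
        mlp = self._toy_positive_mlp()
        rng = np.random.default_rng(0)
        X = rng.uniform(0.1, 1.0, size=(20, 8))
        calib = rng.uniform(0, 1, size=(64, 8))
        snn = convert_ann_to_snn(mlp, calibration=calib)
        est = snn.activation_estimates(X, T=512, encoding="rate", seed=3)[-1]
        acts = mlp.forward(X)
        rel = np.abs(est - acts) / np.maximum(np.abs(acts), 1e-9)
        assert rel.max() < 0.10

    def test_error_decreases_monotonically_in_T(self):
        mlp = build_mlp((8, 6, 4), seed=2)
        rng = np.random.default_rng(0)
        X = rng.uniform(0.1, 1.0, size=(20, 8))
        calib = rng.uniform(0, 1, size=(64, 8))
        snn = convert_ann_to_snn(mlp, calibration=calib)
        acts = mlp.forward(X)
        errs = [
            np.abs(
                snn.activation_estimates(X, T, encoding="rate", seed=3)[-1] - acts
            ).mean()
            for T in (32, 128, 512)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_zero_input_zero_spikes(self):
        mlp = build_mlp((4, 4), seed=0)
        for lin in mlp.linears:
            lin.W.value = np.eye(4)
            lin.b.value[:] = 0.0
        calib = np.random.default_rng(1).uniform(0, 1, size=(16, 4))
        snn = convert_ann_to_snn(mlp, calibration=calib)
        rates = snn.run(np.zeros((3, 4)), T=64, encoding="rate", seed=0)
        assert rates[-1].sum() == 0.0

    def test_weights_identical_up_to_scale(self):
        mlp = build_mlp((8, 6, 4), seed=3)
        calib = np.random.default_rng(2).uniform(0, 1, size=(32, 8))
        snn = convert_ann_to_snn(mlp, calibration=calib)
        prev = 1.0
        for lin_a, lin_s, scale in zip(mlp.linears, snn.linears, snn.scales):
            assert np.allclose(lin_s.W.value, lin_a.W.value * (prev / scale))
            assert np.allclose(lin_s.b.value, lin_a.b.value / scale)
            prev = scale

    def test_architecture_mismatch_names_layer(self):
        mlp = build_mlp((8, 6, 4), seed=0)
        other = convert_ann_to_snn(
            build_mlp((8, 7, 4), seed=0),
            calibration=np.random.default_rng(0).uniform(0, 1, (8, 8)),
        )
        with pytest.raises(ValueError, match="mismatch at layer 0"):
            convert_ann_to_snn(
                mlp,
                calibration=np.random.default_rng(0).uniform(0, 1, (8, 8)),
                target=other,
            )

    def test_ann6_converts_to_matching_snn6(self):
        """Matched-topology transfer: attention copied, FC stack rescaled."""
        ann = build_ann6(2, attn=TINY_ATTN, input_length=20,
                         hidden_sizes=(8, 6, 4), seed=4)
        calib = np.random.default_rng(3).normal(size=(32, 20))
        snn = convert_ann_to_snn(ann, T=64, calibration=calib)
        for p_a, p_s in zip(ann.attention.params(), snn.attention.params()):
            assert np.array_equal(p_a.value, p_s.value)
        assert len(snn.head.linears) == len(ann.head.linears)
        assert snn.head.lif.reset_mode == "subtract"
        X = np.random.default_rng(4).normal(size=(5, 20))
        assert snn.forward(X).shape == (5, 2)
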