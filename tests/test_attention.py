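"""Attention block: simplex preservation, SoftMax identities, gating oracle,
multi-head averaging, conv/pool feature contract."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecg import (
    AttentionConfig,
    apply_attention,
    conv_pool_features,
    head_weights,
    multi_head,
)
from spikecg._nn import softmax
from spikecg.attention import TimeSliceAttention

SMALL = AttentionConfig(
    n_heads=2, slice_count=10, conv_kernels=(3, 3), pool_sizes=(2, 1), seed=0
)


class TestHeadWeights:
    def test_uniform_logits_give_uniform_weights(self):
        w = softmax(np.zeros(7))
        assert np.allclose(w, 1 / 7)

    def test_closed_form_three_slices(self):
        """SoftMax of [1, 0, 0]: e/(e+2), 1/(e+2), 1/(e+2)."""
        w = softmax(np.array([1.0, 0.0, 0.0]))
        e = np.e
        assert np.allclose(w, [e / (e + 2), 1 / (e + 2), 1 / (e + 2)])

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=20)
        assert np.allclose(softmax(logits), softmax(logits + 17.3))

    def test_head_weights_on_simplex(self):
        feats = np.random.default_rng(0).normal(size=10)
        block = TimeSliceAttention(SMALL.slice_count, SMALL)
        for h in range(SMALL.n_heads):
            w = head_weights(feats, h, SMALL, block=block)
            assert w.shape == (SMALL.slice_count,)
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_head_index_out_of_range(self):
        with pytest.raises(IndexError):
            head_weights(np.zeros(10), 5, SMALL)

    def test_permutation_equivariance(self):
        """Permuting logit slices permutes weights identically."""
        rng = np.random.default_rng(4)
        logits = rng.normal(size=8)
        perm = rng.permutation(8)
        assert np.allclose(softmax(logits)[perm], softmax(logits[perm]))


class TestApply:
    def test_uniform_weights_divide_by_slice_count(self):
        x = np.random.default_rng(0).normal(size=12)
        out = apply_attention(x, np.full(12, 1 / 12))
        assert np.allclose(out, x / 12)

    def test_one_hot_selects_single_slice(self):
        x = np.random.default_rng(1).normal(size=(6, 3))
        w = np.zeros(6)
        w[2] = 1.0
        out = apply_attention(x, w)
        assert np.allclose(out[2], x[2])
        assert np.allclose(np.delete(out, 2, axis=0), 0.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(9, 4))
        w = softmax(rng.normal(size=9))
        out = apply_attention(x, w)
        oracle = np.empty_like(x)
        for t in range(9):
            for c in range(4):
                oracle[t, c] = x[t, c] * w[t]
        assert np.max(np.abs(out - oracle)) < 1e-12

    def test_length_mismatch_names_both(self):
        with pytest.raises(ValueError, match="9.*4|4.*9"):
            apply_attention(np.zeros(9), np.zeros(4))


class TestMultiHead:
    def test_single_head_averaged_equals_head(self):
        cfg = AttentionConfig(
            n_heads=1, slice_count=10, conv_kernels=(3, 3), pool_sizes=(2, 1), seed=1
        )
        w, _ = multi_head(np.random.default_rng(0).normal(size=20), cfg)
        assert np.allclose(w.averaged, w.per_head[0])

    def test_two_heads_average_hand_case(self):
        """Hand-set projections: averaged weights are the mean of the two."""
        block = TimeSliceAttention(SMALL.slice_count, SMALL)
        for i, h in enumerate(block.heads):
            h.W.value[:] = 0.0
            h.b.value[:] = 0.0
            h.b.value[i] = 1.0  # head i prefers slice i
        x = np.random.default_rng(5).normal(size=(1, SMALL.slice_count))
        w, _ = block.weights(x)
        a = softmax(np.eye(SMALL.slice_count)[0])
        b = softmax(np.eye(SMALL.slice_count)[1])
        assert np.allclose(w.per_head[0, 0], a)
        assert np.allclose(w.per_head[1, 0], b)
        assert np.allclose(w.averaged[0], (a + b) / 2)

    def test_averaged_on_simplex_across_seeds(self):
        rng = np.random.default_rng(0)
        for seed in range(100):
            cfg = AttentionConfig(
                n_heads=3, slice_count=10, conv_kernels=(3, 3),
                pool_sizes=(2, 1), seed=seed,
            )
            x = rng.normal(size=20) * rng.uniform(0.1, 10)
            w, gated = multi_head(x, cfg)
            assert np.all(w.per_head >= 0)
            assert np.allclose(w.per_head.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(w.averaged >= 0)
            assert w.averaged.sum() == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 100.0))
    def test_simplex_for_arbitrary_inputs(self, seed, scale):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=501) * scale
        w, _ = multi_head(x, AttentionConfig(seed=seed % 1000))
        assert np.all(w.averaged >= 0)
        assert w.averaged.sum() == pytest.approx(1.0, abs=1e-6)


class TestConvPool:
    def test_output_depth_is_two(self):
        x = np.random.default_rng(0).normal(size=501)
        cfg = AttentionConfig()
        feats = conv_pool_features(x, cfg)
        # flattened (channels, time) map: depth 2 folded into the length
        assert feats.size == 2 * ((cfg.slice_count // 2) // 2)

    def test_identity_kernels_replicate_input(self):
        """Centre-tap kernels with pool size 1 copy the input per channel."""
        cfg = AttentionConfig(
            n_heads=1, slice_count=10, conv_kernels=(3, 3), pool_sizes=(1, 1), seed=0
        )
        block = TimeSliceAttention(cfg.slice_count, cfg)
        block.conv1.W.value[:] = 0.0
        block.conv1.b.value[:] = 0.0
        block.conv1.W.value[:, 0, 1] = 1.0  # both channels copy the input
        block.conv2.W.value[:] = 0.0
        block.conv2.b.value[:] = 0.0
        for c in range(2):
            block.conv2.W.value[c, c, 1] = 1.0
        x = np.abs(np.random.default_rng(1).normal(size=(1, 10)))  # ReLU-safe
        feats = block.features(x)
        assert np.allclose(feats.reshape(2, 10), np.vstack([x[0], x[0]]))

    def test_all_ones_input_matches_hand_convolution(self):
        """Brute-force direct convolution oracle, including border effects."""
        cfg = AttentionConfig(
            n_heads=1, slice_count=12, conv_kernels=(3, 3), pool_sizes=(2, 1), seed=7
        )
        block = TimeSliceAttention(cfg.slice_count, cfg)
        x = np.ones((1, 12))

        def conv_same(inp, W, b):  # inp (C,L)
            c_out, c_in, k = W.shape
            pad = k // 2
            padded = np.pad(inp, ((0, 0), (pad, pad)))
            out = np.zeros((c_out, inp.shape[1]))
            for o in range(c_out):
                for t in range(inp.shape[1]):
                    out[o, t] = b[o] + sum(
                        W[o, c, kk] * padded[c, t + kk]
                        for c in range(c_in)
                        for kk in range(k)
                    )
            return out

        z = conv_same(x, block.conv1.W.value, block.conv1.b.value)
        z = np.maximum(z, 0)
        z = z[:, : (z.shape[1] // 2) * 2].reshape(z.shape[0], -1, 2).mean(axis=2)
        z = conv_same(z, block.conv2.W.value, block.conv2.b.value)
        z = np.maximum(z, 0)
        assert np.allclose(block.features(x)[0], z.reshape(-1), atol=1e-12)

    def test_too_short_input_raises(self):
        cfg = AttentionConfig(
            n_heads=1, slice_count=2, conv_kernels=(5, 3), pool_sizes=(1, 1), seed=0
        )
        block = TimeSliceAttention(2, cfg)
        with pytest.raises(ValueError, match="shorter"):
            block.features(np.ones((1, 2)))
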