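"""Splits, training harness, metrics reporter, timestep sweep."""

from __future__ import annotations

import numpy as np
import pytest

from spikecg import (
    AttentionConfig,
    AttentionSNNClassifier,
    BeatSegment,
    MetricsReport,
    SplitSpec,
    TrainConfig,
    evaluate,
    make_split,
    metrics_from_confusion,
    timestep_sweep,
    train,
)
from spikecg.train_eval import confusion_matrix

TINY = dict(
    slice_count=10,
    n_heads=2,
    hidden_layer_sizes=(8, 6),
    timesteps=4,
)


def _segments(n, n_classes=2, length=20, record_ids=("a",), seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = f"c{i % n_classes}"
        base = np.zeros(length)
        base[5 + 3 * (i % n_classes)] = 2.0  # class-dependent bump
        out.append(
            BeatSegment(
                samples=base + 0.2 * rng.normal(size=length),
                label=label,
                record_id=record_ids[i % len(record_ids)],
                rpeak_index=100 + i,
            )
        )
    return out


class TestSplit:
    def test_random_7030_counts(self):
        tr, te = make_split(_segments(100), SplitSpec(seed=1))
        assert len(tr) == 70 and len(te) == 30

    def test_same_seed_identical(self):
        segs = _segments(60)
        a = make_split(segs, SplitSpec(seed=5))
        b = make_split(segs, SplitSpec(seed=5))
        assert [s.rpeak_index for s in a[0]] == [s.rpeak_index for s in b[0]]

    def test_stratification_within_one_segment(self):
        segs = _segments(101, n_classes=2)
        tr, te = make_split(segs, SplitSpec(seed=0))
        frac = lambda ss: sum(s.label == "c0" for s in ss) / len(ss)
        overall = frac(segs)
        assert abs(frac(tr) - overall) <= 1 / len(tr) + 1e-9
        assert abs(frac(te) - overall) <= 1 / len(te) + 1e-9

    def test_inter_patient_disjoint_by_record(self):
        segs = _segments(40, record_ids=("100", "101"))
        spec = SplitSpec(
            strategy="inter_patient", train_records=("101",), test_records=("100",)
        )
        tr, te = make_split(segs, spec)
        assert {s.record_id for s in tr} == {"101"}
        assert {s.record_id for s in te} == {"100"}
        assert not {s.record_id for s in tr} & {s.record_id for s in te}

    def test_inter_patient_unlisted_record_errors(self):
        segs = _segments(4, record_ids=("999",))
        spec = SplitSpec(
            strategy="inter_patient", train_records=("1",), test_records=("2",)
        )
        with pytest.raises(ValueError, match="999"):
            make_split(segs, spec)

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitSpec(strategy="inter_patient",
                      train_records=("1", "2"), test_records=("2", "3"))


class TestTrain:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        segs = _segments(8)
        clf = AttentionSNNClassifier(
            **TINY, epochs=1, batch_size=8, learning_rate=0.0, random_state=0
        )
        X = np.stack([s.samples for s in segs])
        y = [s.label for s in segs]
        clf.fit(X, y)
        ref = AttentionSNNClassifier(**TINY, epochs=1, random_state=0)
        net = ref._build(X.shape[1], 2)
        for p_trained, p_init in zip(clf.network_.params(), net.params()):
            assert np.array_equal(p_trained.value, p_init.value)

    def test_loss_decreases_on_separable_data(self):
        segs = _segments(60)
        fitted, history = train(
            AttentionSNNClassifier(**TINY),
            segs,
            TrainConfig(epochs=10, timesteps=4, seed=0),
        )
        assert history[-1] < history[0]

    def test_loss_history_bitwise_reproducible(self):
        segs = _segments(40)
        cfg = TrainConfig(epochs=4, timesteps=4, seed=3)
        _, h1 = train(AttentionSNNClassifier(**TINY), segs, cfg)
        _, h2 = train(AttentionSNNClassifier(**TINY), segs, cfg)
        assert h1 == h2

    def test_divergence_aborts_with_epoch(self):
        """An exploding step drives the conventional net's logits non-finite;
        the loop must abort naming the epoch (spike-count logits are bounded,
        so the spiking model cannot diverge this way)."""
        from spikecg import ConvNetClassifier

        segs = _segments(32, length=24)
        clf = ConvNetClassifier(
            conv_channels=(4, 4, 4), fc_sizes=(8, 8, 8),
            epochs=10, learning_rate=1e100, random_state=0,
        )
        X = np.stack([s.samples for s in segs])
        y = [s.label for s in segs]
        with pytest.raises(FloatingPointError, match="epoch"):
            clf.fit(X, y)


class TestMetrics:
    def test_perfect_predictions(self):
        cm = confusion_matrix(["a", "b", "a"], ["a", "b", "a"], ("a", "b"))
        rep = metrics_from_confusion(cm, ("a", "b"))
        assert rep.overall_accuracy == 1.0
        assert all(v == 1.0 for v in rep.f1.values())

    def test_hand_computed_two_class_matrix(self):
        """[[8,2],[3,7]]: accuracy .75; class-0 P=8/11, R=.8, F1 by hand."""
        cm = np.array([[8, 2], [3, 7]])
        rep = metrics_from_confusion(cm, ("0", "1"))
        assert rep.overall_accuracy == pytest.approx(0.75)
        assert rep.precision["0"] == pytest.approx(8 / 11)
        assert rep.sensitivity["0"] == pytest.approx(0.8)
        p, s = 8 / 11, 0.8
        assert rep.f1["0"] == pytest.approx(2 * p * s / (p + s))

    def test_conservation_and_row_sums(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["a", "b", "c"], size=200)
        pred = rng.choice(["a", "b", "c"], size=200)
        cm = confusion_matrix(y, pred, ("a", "b", "c"))
        assert cm.sum() == 200
        for i, c in enumerate(("a", "b", "c")):
            assert cm[i].sum() == np.sum(y == c)

    def test_undefined_cells_flagged_not_zeroed(self):
        cm = np.array([[5, 0], [0, 0]])  # class 1 never occurs nor predicted
        rep = metrics_from_confusion(cm, ("0", "1"))
        assert "1" in rep.undefined
        assert np.isnan(rep.precision["1"])
        assert rep.overall_accuracy == 1.0

    def test_null_predictions_near_half_accuracy(self):
        rng = np.random.default_rng(7)
        n = 4000
        y = rng.choice(["a", "b"], size=n)
        pred = rng.choice(["a", "b"], size=n)
        cm = confusion_matrix(y, pred, ("a", "b"))
        rep = metrics_from_confusion(cm, ("a", "b"))
        se = np.sqrt(0.25 / n)
        assert abs(rep.overall_accuracy - 0.5) <= 3 * se

    def test_micro_average_equals_accuracy(self):
        rng = np.random.default_rng(1)
        cm = rng.integers(0, 30, size=(3, 3))
        rep = metrics_from_confusion(cm, ("a", "b", "c"), average="micro")
        assert rep.macro_f1 == pytest.approx(rep.overall_accuracy)


class TestSweep:
    def test_single_value_single_row(self):
        segs = _segments(40)
        tr, te = make_split(segs, SplitSpec(seed=0))
        table = timestep_sweep(
            AttentionSNNClassifier(**TINY), tr, te, [1],
            TrainConfig(epochs=2, seed=0),
        )
        assert list(table.columns) == ["T", "accuracy"]
        assert len(table) == 1

    def test_duplicate_T_identical_accuracy(self):
        segs = _segments(40)
        tr, te = make_split(segs, SplitSpec(seed=0))
        table = timestep_sweep(
            AttentionSNNClassifier(**TINY), tr, te, [3, 3],
            TrainConfig(epochs=2, seed=0),
        )
        assert table.accuracy.iloc[0] == table.accuracy.iloc[1]
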