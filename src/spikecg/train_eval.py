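"""Evaluation protocols: splits, training harness, metrics, timestep sweep.

Two split strategies are supported: the seeded, class-stratified random
70:30 split over segments, and the inter-patient split that assigns whole
records (patients) to either side so no patient contributes to both.  The
default inter-patient record lists for MIT-BIH live in :mod:`spikecg.io`.

The metrics reporter computes everything from the confusion matrix by hand
(precision, sensitivity/recall, F1 per class, macro/micro/weighted summary,
overall accuracy); zero-denominator cells are reported as NaN with an
explicit flag rather than silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import train_test_split

from .io import INTER_PATIENT_TEST_RECORDS, INTER_PATIENT_TRAIN_RECORDS
from .preprocess import BeatSegment, segments_to_arrays

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "MetricsReport",
    "make_split",
    "train",
    "evaluate",
    "confusion_matrix",
    "metrics_from_confusion",
    "timestep_sweep",
]


@dataclass(frozen=True)
class SplitSpec:
    """How to divide segments into train and test sets."""

    strategy: str = "random_7030"
    seed: int = 0
    test_fraction: float = 0.3
    train_records: tuple = tuple(str(r) for r in INTER_PATIENT_TRAIN_RECORDS)
    test_records: tuple = tuple(str(r) for r in INTER_PATIENT_TEST_RECORDS)

    def __post_init__(self) -> None:
        if self.strategy not in {"random_7030", "inter_patient"}:
            raise ValueError("strategy must be 'random_7030' or 'inter_patient'")
        if self.strategy == "inter_patient":
            overlap = set(self.train_records) & set(self.test_records)
            if overlap:
                raise ValueError(f"record lists overlap: {sorted(overlap)}")


@dataclass(frozen=True)
class TrainConfig:
    """Published training hyperparameters as defaults."""

    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 64
    timesteps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.timesteps) < 1 or self.learning_rate <= 0:
            raise ValueError("all training hyperparameters must be positive")


@dataclass
class MetricsReport:
    """Confusion matrix and the derived classification metrics."""

    classes: tuple[str, ...]
    confusion_matrix: np.ndarray
    overall_accuracy: float
    precision: dict[str, float]
    sensitivity: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    macro_precision: float
    macro_sensitivity: float
    macro_f1: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "support": self.support,
            "macro_precision": self.macro_precision,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_f1": self.macro_f1,
            "undefined": list(self.undefined),
        }


def make_split(
    segments: list[BeatSegment], spec: SplitSpec = SplitSpec()
) -> tuple[list[BeatSegment], list[BeatSegment]]:
    """Split segments per the chosen protocol."""
    if not segments:
        raise ValueError("no segments to split")
    if spec.strategy == "random_7030":
        labels = [s.label for s in segments]
        idx_train, idx_test = train_test_split(
            np.arange(len(segments)),
            test_size=spec.test_fraction,
            random_state=spec.seed,
            stratify=labels,
        )
        return [segments[i] for i in idx_train], [segments[i] for i in idx_test]

    train_ids = set(spec.train_records)
    test_ids = set(spec.test_records)
    train_set, test_set = [], []
    for s in segments:
        if s.record_id in train_ids:
            train_set.append(s)
        elif s.record_id in test_ids:
            test_set.append(s)
        else:
            raise ValueError(
                f"record id {s.record_id!r} is in neither inter-patient list"
            )
    return train_set, test_set


def train(
    estimator,
    train_segments: list[BeatSegment],
    config: TrainConfig = TrainConfig(),
):
    """Fit a (cloned) classifier on segments under the given hyperparameters.

    Returns ``(fitted_estimator, loss_history)``.  Only hyperparameters the
    estimator exposes are overridden, so the same harness drives both the
    spiking model (which has ``timesteps``) and the conventional baseline.
    """
    X, y = segments_to_arrays(train_segments)
    est = clone(estimator)
    params = {
        "epochs": config.epochs,
        "learning_rate": config.learning_rate,
        "batch_size": config.batch_size,
        "random_state": config.seed,
        "timesteps": config.timesteps,
    }
    valid = est.get_params()
    est.set_params(**{k: v for k, v in params.items() if k in valid})
    est.fit(X, y)
    return est, list(est.loss_history_)


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, classes: tuple[str, ...]
) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[str(t)], index[str(p)]] += 1
    return cm


def metrics_from_confusion(
    cm: np.ndarray, classes: tuple[str, ...], average: str = "macro"
) -> MetricsReport:
    cm = np.asarray(cm)
    total = int(cm.sum())
    accuracy = float(np.trace(cm) / total) if total else float("nan")
    precision, sensitivity, f1, support = {}, {}, {}, {}
    undefined: list[str] = []
    for i, c in enumerate(classes):
        tp = float(cm[i, i])
        fp = float(cm[:, i].sum() - tp)
        fn = float(cm[i, :].sum() - tp)
        support[c] = int(cm[i, :].sum())
        p = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
        s = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        if np.isnan(p) or np.isnan(s):
            undefined.append(c)
            f_val = float("nan")
        elif p + s == 0:
            f_val = 0.0
        else:
            f_val = 2 * p * s / (p + s)
        precision[c], sensitivity[c], f1[c] = p, s, f_val

    def _avg(d: dict[str, float]) -> float:
        vals = np.array(list(d.values()), dtype=float)
        if average == "macro":
            return float(np.nanmean(vals))
        if average == "weighted":
            w = np.array([support[c] for c in classes], dtype=float)
            mask = ~np.isnan(vals)
            return float(np.sum(vals[mask] * w[mask]) / np.sum(w[mask]))
        if average == "micro":
            return accuracy  # single-label multi-class micro P = R = accuracy
        raise ValueError(f"unknown average {average!r}")

    return MetricsReport(
        classes=tuple(classes),
        confusion_matrix=cm,
        overall_accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        f1=f1,
        support=support,
        macro_precision=_avg(precision),
        macro_sensitivity=_avg(sensitivity),
        macro_f1=_avg(f1),
        undefined=tuple(undefined),
    )


def evaluate(
    estimator,
    test_segments: list[BeatSegment],
    average: str = "macro",
) -> MetricsReport:
    """Score a fitted classifier on held-out segments."""
    if not test_segments:
        raise ValueError("test set is empty")
    X, y = segments_to_arrays(test_segments)
    y_pred = estimator.predict(X)
    classes = tuple(str(c) for c in estimator.classes_)
    extra = sorted(set(map(str, y)) - set(classes))
    classes = classes + tuple(extra)
    cm = confusion_matrix(y, y_pred, classes)
    return metrics_from_confusion(cm, classes, average=average)


def timestep_sweep(
    estimator,
    train_segments: list[BeatSegment],
    test_segments: list[BeatSegment],
    T_values: list[int],
    config: TrainConfig = TrainConfig(),
) -> pd.DataFrame:
    """Train/evaluate at each simulation length T with a shared seed.

    Returns a table with columns ``T`` and ``accuracy`` — the data behind
    the accuracy-versus-timesteps analysis.
    """
    if not T_values:
        raise ValueError("T_values must be non-empty")
    rows = []
    for T in T_values:
        cfg = TrainConfig(
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            timesteps=int(T),
            seed=config.seed,
        )
        fitted, _ = train(estimator, train_segments, cfg)
        report = evaluate(fitted, test_segments)
        rows.append({"T": int(T), "accuracy": report.overall_accuracy})
    return pd.DataFrame(rows)
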