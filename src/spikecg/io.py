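"""Record I/O and label mapping.

Two on-disk layouts are supported:

* ``csv_pair`` — a plain-text dialect used throughout this package: a
  waveform CSV ``<stem>.signal.csv`` whose first line is a metadata comment
  (``# record_id=...,sampling_rate=...[,record_label=...]``) followed by
  ``sample_index,value`` rows, plus an annotation CSV ``<stem>.ann.csv`` with
  ``sample_index,label`` rows (absent for record-level-labelled records).
* ``wfdb`` — PhysioBank records, available only when the optional ``wfdb``
  package is installed; real MIT-BIH / PhysioNet data are never required.

The module also holds the MIT-BIH record-selection constants used by the
evaluation protocols: the four excluded records and the two disjoint
inter-patient record lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import ECGRecord

__all__ = [
    "MITBIH_EXCLUDED_RECORDS",
    "INTER_PATIENT_TRAIN_RECORDS",
    "INTER_PATIENT_TEST_RECORDS",
    "AAMI_LABEL_MAP",
    "PHYSIONET2017_CLASSES",
    "LabelMap",
    "read_record",
    "write_record",
    "map_labels",
]

# Records withheld from the MIT-BIH arrhythmia protocol (paced or unsuitable).
MITBIH_EXCLUDED_RECORDS: tuple[int, ...] = (102, 104, 107, 217)

# Disjoint record lists for the inter-patient protocol (train on one set of
# patients, test on completely different patients).
INTER_PATIENT_TRAIN_RECORDS: tuple[int, ...] = (
    101, 106, 108, 109, 112, 114, 115, 116, 118, 119, 122,
    124, 201, 203, 205, 207, 208, 209, 215, 220, 223, 230,
)
INTER_PATIENT_TEST_RECORDS: tuple[int, ...] = (
    100, 103, 105, 111, 113, 117, 121, 123, 200, 202, 210,
    212, 213, 214, 219, 221, 222, 228, 231, 232, 233, 234,
)

PHYSIONET2017_CLASSES: tuple[str, ...] = ("N", "AF", "O", "~")


@dataclass(frozen=True)
class LabelMap:
    """Mapping from native annotation symbols to analysis class symbols.

    A native symbol mapped to ``"drop"`` removes the beat (and its R peak).
    """

    mapping: dict[str, str]
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.class_order)) != len(self.class_order):
            raise ValueError("class_order contains duplicates")
        bad = {
            v for v in self.mapping.values() if v != "drop" and v not in self.class_order
        }
        if bad:
            raise ValueError(f"mapped classes not in class_order: {sorted(bad)}")


# The five AAMI-style heartbeat super-classes over MIT-BIH native symbols:
# N (normal & bundle-branch), S (supraventricular ectopic), V (ventricular
# ectopic), F (fusion), Q (paced/unknown).
AAMI_LABEL_MAP = LabelMap(
    mapping={
        "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
        "A": "S", "a": "S", "J": "S", "S": "S",
        "V": "V", "E": "V",
        "F": "F",
        "/": "Q", "f": "Q", "Q": "Q",
    },
    class_order=("N", "S", "V", "F", "Q"),
)


def _signal_path(stem: Path) -> Path:
    return stem.with_suffix(stem.suffix + ".signal.csv")


def _ann_path(stem: Path) -> Path:
    return stem.with_suffix(stem.suffix + ".ann.csv")


def write_record(record: ECGRecord, stem: str | Path) -> None:
    """Write a record in the csv_pair layout under path stem ``stem``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    meta = (
        f"# record_id={record.record_id},"
        f"sampling_rate={float(record.sampling_rate):.17g}"
    )
    if record.record_label is not None:
        meta += f",record_label={record.record_label}"
    with open(_signal_path(stem), "w") as fh:
        fh.write(meta + "\n")
        fh.write("sample_index,value\n")
        for i, v in enumerate(record.signal):
            fh.write(f"{i},{float(v):.17g}\n")
    if record.beat_labels is not None:
        ann = pd.DataFrame(
            {"sample_index": record.rpeak_indices, "label": record.beat_labels}
        )
    else:
        ann = pd.DataFrame(
            {"sample_index": record.rpeak_indices,
             "label": [""] * record.rpeak_indices.size}
        )
    ann.to_csv(_ann_path(stem), index=False)


def _parse_meta(line: str) -> dict[str, str]:
    if not line.startswith("#"):
        raise ValueError("csv_pair signal file must start with a '# ...' metadata line")
    out: dict[str, str] = {}
    for item in line.lstrip("#").strip().split(","):
        key, _, val = item.partition("=")
        out[key.strip()] = val.strip()
    return out


def _read_csv_pair(stem: Path) -> ECGRecord:
    sig_path = _signal_path(stem)
    with open(sig_path) as fh:
        meta = _parse_meta(fh.readline())
    df = pd.read_csv(sig_path, skiprows=1)
    signal = df["value"].to_numpy(dtype=float)
    record_id = meta.get("record_id", stem.name)
    sampling_rate = float(meta["sampling_rate"])
    record_label = meta.get("record_label")

    rpeaks = np.empty(0, dtype=int)
    beat_labels: list[str] | None = None
    ann_path = _ann_path(stem)
    if ann_path.exists():
        ann = pd.read_csv(ann_path, keep_default_na=False, dtype={"label": str})
        rpeaks = ann["sample_index"].to_numpy(dtype=int)
        labels = [str(x) for x in ann["label"]]
        if any(labels):
            beat_labels = labels
        if rpeaks.size and (rpeaks.min() < 0 or rpeaks.max() >= signal.size):
            raise ValueError(
                f"record {record_id!r}: annotation index out of signal range "
                f"(signal length {signal.size})"
            )
    if beat_labels is None and record_label is None:
        raise ValueError(f"record {record_id!r}: no beat labels and no record label")
    return ECGRecord(
        record_id=record_id,
        signal=signal,
        sampling_rate=sampling_rate,
        rpeak_indices=rpeaks,
        beat_labels=beat_labels,
        record_label=record_label,
    )


def _read_wfdb(stem: Path, channel: int = 0) -> ECGRecord:
    try:
        import wfdb  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install spikecg[wfdb])"
        ) from exc
    rec = wfdb.rdrecord(str(stem))  # pragma: no cover - optional dependency
    ann = wfdb.rdann(str(stem), "atr")
    signal = np.asarray(rec.p_signal)[:, channel]
    rpeaks = np.asarray(ann.sample, dtype=int)
    labels = [str(s) for s in ann.symbol]
    if rpeaks.size and (rpeaks.min() < 0 or rpeaks.max() >= signal.size):
        raise ValueError(f"record {stem.name!r}: annotation index out of signal range")
    return ECGRecord(
        record_id=stem.name,
        signal=signal,
        sampling_rate=float(rec.fs),
        rpeak_indices=rpeaks,
        beat_labels=labels,
    )


def read_record(
    path: str | Path,
    format: str = "csv_pair",
    label_map: LabelMap | None = None,
    on_unmapped: str = "error",
) -> ECGRecord:
    """Read a record; ``path`` is the stem shared by the layout's files."""
    stem = Path(path)
    if format == "csv_pair":
        record = _read_csv_pair(stem)
    elif format == "wfdb":
        record = _read_wfdb(stem)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'wfdb' or 'csv_pair')")
    if label_map is not None:
        record = map_labels(record, label_map, on_unmapped=on_unmapped)
    return record


def map_labels(
    record: ECGRecord, label_map: LabelMap, on_unmapped: str = "error"
) -> ECGRecord:
    """Replace native annotation symbols with analysis class symbols.

    ``on_unmapped="error"`` (strict) raises on any symbol outside the map;
    ``on_unmapped="drop"`` removes those beats together with their R peaks.
    Symbols explicitly mapped to ``"drop"`` are always removed.
    """
    if on_unmapped not in {"error", "drop"}:
        raise ValueError("on_unmapped must be 'error' or 'drop'")
    if record.beat_labels is None:
        if record.record_label is None:
            return record
        native = record.record_label
        if native not in label_map.mapping:
            if on_unmapped == "error":
                raise KeyError(f"unmapped record label {native!r}")
            return record
        return ECGRecord(
            record_id=record.record_id,
            signal=record.signal,
            sampling_rate=record.sampling_rate,
            rpeak_indices=record.rpeak_indices,
            record_label=label_map.mapping[native],
        )

    unmapped = sorted(set(record.beat_labels) - set(label_map.mapping))
    if unmapped and on_unmapped == "error":
        raise KeyError(f"unmapped beat symbols: {unmapped}")

    keep_idx, new_labels = [], []
    for i, sym in enumerate(record.beat_labels):
        target = label_map.mapping.get(sym)
        if target is None or target == "drop":
            continue
        keep_idx.append(i)
        new_labels.append(target)
    return ECGRecord(
        record_id=record.record_id,
        signal=record.signal,
        sampling_rate=record.sampling_rate,
        rpeak_indices=record.rpeak_indices[keep_idx],
        beat_labels=new_labels,
        record_label=record.record_label,
    )
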