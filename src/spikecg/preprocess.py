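"""Signal conditioning: wavelet denoising, R-peak handling, beat segmentation.

The pipeline mirrors standard single-lead arrhythmia practice: the raw
waveform is denoised by wavelet thresholding, annotated R-peak positions are
re-aligned to the true local extrema of the denoised trace, and a fixed
window of ``half_window`` samples on either side of each R peak is cut out
as one beat segment.  The first beats of every record are discarded as a
transient; beats whose window would overrun the record are skipped rather
than padded, so every segment has the exact invariant length
``2 * half_window + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .synth import ECGRecord

__all__ = [
    "DenoiseConfig",
    "SegmentConfig",
    "BeatSegment",
    "denoise",
    "realign_rpeaks",
    "segment",
    "detect_rpeaks",
    "segments_to_arrays",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DenoiseConfig:
    """Wavelet-thresholding settings.

    Defaults follow common ECG practice at 360 samples/s: a Daubechies-6
    mother wavelet decomposed to level 6, the universal threshold
    ``sigma * sqrt(2 ln N)`` with the noise scale ``sigma`` estimated from
    the median absolute deviation of the finest detail level, applied in
    soft (shrinkage) mode to all detail coefficients.
    """

    wavelet_name: str = "db6"
    decomposition_level: int = 6
    threshold_rule: str = "universal"
    threshold_mode: str = "soft"

    def __post_init__(self) -> None:
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        if self.threshold_rule not in {"universal", "sure"}:
            raise ValueError("threshold_rule must be 'universal' or 'sure'")
        if self.threshold_mode not in {"soft", "hard"}:
            raise ValueError("threshold_mode must be 'soft' or 'hard'")


@dataclass(frozen=True)
class SegmentConfig:
    """Beat-window settings: +-``half_window`` samples around each R peak,
    skipping the first ``skip_first_beats`` beats of every record."""

    half_window: int = 250
    skip_first_beats: int = 15
    realign_radius: int = 25

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ValueError("half_window must be >= 1")
        if self.skip_first_beats < 0:
            raise ValueError("skip_first_beats must be >= 0")
        if self.realign_radius < 0:
            raise ValueError("realign_radius must be >= 0")


@dataclass
class BeatSegment:
    """One fixed-length heartbeat window."""

    samples: np.ndarray
    label: str
    record_id: str
    rpeak_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("segment samples must be one-dimensional")


def _sure_threshold(detail: np.ndarray, sigma: float) -> float:
    """Stein's unbiased risk threshold for one detail band."""
    n = detail.size
    if n == 0 or sigma == 0:
        return 0.0
    x2 = np.sort((detail / sigma) ** 2)
    cum = np.cumsum(x2)
    ks = np.arange(1, n + 1)
    # risk(t_k) with t_k^2 = x2[k-1]: n - 2k + sum(min(x2, t_k^2))
    risk = n - 2.0 * ks + (cum + (n - ks) * x2)
    best = int(np.argmin(risk))
    return float(sigma * np.sqrt(x2[best]))


def denoise(signal: np.ndarray, config: DenoiseConfig = DenoiseConfig()) -> np.ndarray:
    """Wavelet-threshold a 1-D signal; output has the input's length."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    wavelet = pywt.Wavelet(config.wavelet_name)
    max_level = pywt.dwt_max_level(x.size, wavelet.dec_len)
    if config.decomposition_level > max_level:
        raise ValueError(
            f"decomposition_level {config.decomposition_level} infeasible for "
            f"signal length {x.size}; maximum feasible level is {max_level}"
        )
    coeffs = pywt.wavedec(x, wavelet, level=config.decomposition_level)
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest)) / 0.6745) if finest.size else 0.0
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        if config.threshold_rule == "universal":
            thr = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))
        else:
            thr = _sure_threshold(detail, sigma)
        if thr > 0:
            detail = pywt.threshold(detail, thr, mode=config.threshold_mode)
        out.append(detail)
    rec = pywt.waverec(out, wavelet)
    return rec[: x.size]


def realign_rpeaks(
    signal: np.ndarray, peaks: np.ndarray, radius: int
) -> np.ndarray:
    """Snap each annotated peak to the argmax of ``|signal|`` within
    ``+-radius`` samples; ties break toward the annotated index.  Peaks that
    collide after realignment are deduplicated keeping the first."""
    x = np.asarray(signal, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if peaks.size and (peaks.min() < 0 or peaks.max() >= x.size):
        raise ValueError("peaks out of signal bounds")
    if radius == 0:
        return peaks.copy()

    out: list[int] = []
    for p in peaks:
        lo = max(0, p - radius)
        hi = min(x.size, p + radius + 1)
        window = np.abs(x[lo:hi])
        best = window.max()
        cands = lo + np.flatnonzero(window == best)
        new = int(cands[np.argmin(np.abs(cands - p))])
        out.append(new)

    result: list[int] = []
    dropped = 0
    for idx in out:
        if result and idx <= result[-1]:
            dropped += 1
            continue
        result.append(idx)
    if dropped:
        logger.warning("realign_rpeaks: dropped %d colliding peak(s)", dropped)
    return np.asarray(result, dtype=int)


def segment(
    record: ECGRecord, config: SegmentConfig = SegmentConfig()
) -> list[BeatSegment]:
    """Cut fixed-length beat windows from an annotated record.

    For beat-labelled records the segment label is the beat's class; for
    record-labelled records every segment inherits the record label.  The
    first ``skip_first_beats`` beats are discarded and windows that would
    overrun the signal are skipped (counted in the run log).
    """
    if record.beat_labels is None and record.record_label is None:
        raise ValueError("record carries neither beat labels nor a record label")
    h = config.half_window
    n = record.signal.size
    peaks = record.rpeak_indices
    labels = (
        record.beat_labels
        if record.beat_labels is not None
        else [record.record_label] * peaks.size
    )

    segments: list[BeatSegment] = []
    skipped_bounds = 0
    for peak, label in list(zip(peaks, labels))[config.skip_first_beats:]:
        lo, hi = peak - h, peak + h + 1
        if lo < 0 or hi > n:
            skipped_bounds += 1
            continue
        segments.append(
            BeatSegment(
                samples=record.signal[lo:hi],
                label=str(label),
                record_id=record.record_id,
                rpeak_index=int(peak),
            )
        )
    if skipped_bounds:
        logger.info(
            "segment: record %s: skipped %d out-of-bounds window(s)",
            record.record_id,
            skipped_bounds,
        )
    return segments


def detect_rpeaks(signal: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Derivative-energy QRS detector with refractory lockout.

    A Pan–Tompkins-style chain: 5–15 Hz band-pass, differentiation,
    squaring, moving-window integration, adaptive-threshold peak picking
    with a 250 ms minimum inter-peak distance, then refinement of each
    detection to the local absolute maximum of the band-passed trace.
    Returns an empty list for (near-)constant input.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 8 or np.ptp(x) == 0:
        return np.empty(0, dtype=int)
    fs = float(sampling_rate)
    nyq = fs / 2.0
    lo, hi = 5.0 / nyq, min(15.0 / nyq, 0.99)
    sos = sps.butter(2, [lo, hi], btype="band", output="sos")
    band = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(band)
    energy = deriv**2
    win = max(1, int(round(0.15 * fs)))
    mwi = np.convolve(energy, np.ones(win) / win, mode="same")

    height = 0.2 * np.quantile(mwi, 0.995)
    if height <= 0:
        return np.empty(0, dtype=int)
    distance = max(1, int(round(0.25 * fs)))
    locs, _ = sps.find_peaks(mwi, height=height, distance=distance)

    refine = max(1, int(round(0.10 * fs)))
    peaks = []
    for loc in locs:
        a = max(0, loc - refine)
        b = min(x.size, loc + refine + 1)
        peaks.append(a + int(np.argmax(np.abs(band[a:b]))))
    peaks = sorted(set(peaks))
    out: list[int] = []
    for p in peaks:
        if out and p - out[-1] < distance:
            continue
        out.append(p)
    return np.asarray(out, dtype=int)


def segments_to_arrays(segments: list[BeatSegment]) -> tuple[np.ndarray, np.ndarray]:
    """Stack segments into ``X`` of shape (n_segments, window) and label
    array ``y`` — the layout the classifiers consume."""
    if not segments:
        raise ValueError("no segments")
    X = np.stack([s.samples for s in segments])
    y = np.asarray([s.label for s in segments])
    return X, y
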