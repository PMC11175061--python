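"""Synthetic single-lead ECG generator with known ground truth.

Every downstream stage of the pipeline (denoising, R-peak realignment,
segmentation, encoding, classification) is testable against records produced
here, because the generator knows the exact clean waveform, the exact R-peak
sample positions and the class of every beat.

A beat is a sum of five Gaussian bumps (P, Q, R, S, T) whose amplitudes,
centres and widths depend on the beat class.  Records are quasi-periodic
trains of such beats at jittered RR intervals, optionally corrupted by
additive white Gaussian noise, a low-frequency baseline-wander sinusoid and
a powerline sinusoid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynthConfig",
    "ECGRecord",
    "BEAT_TEMPLATES",
    "RECORD_CLASS_PRESETS",
    "beat_template",
    "clean_signal",
    "generate_record",
    "generate_dataset",
    "noise_sd_for_snr",
]

# Per-class wave parameters: (amplitude [mV], centre [s relative to R], width [s]).
# "N" is a textbook sinus beat.  "V" is a ventricular-ectopic-like beat: no P
# wave, a wide low R with deep slurred S, and an inverted T.  "S" is an
# atrial-premature-like beat (normal narrow QRS, flattened early P).  "F" is a
# fusion of N and V morphology; "Q" is a low-amplitude ambiguous complex.
BEAT_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "N": {
        "P": (0.12, -0.20, 0.025),
        "Q": (-0.15, -0.035, 0.010),
        "R": (1.00, 0.0, 0.012),
        "S": (-0.25, 0.035, 0.010),
        "T": (0.30, 0.30, 0.060),
    },
    "V": {
        "P": (0.0, -0.20, 0.025),
        "Q": (-0.10, -0.060, 0.030),
        "R": (0.90, 0.0, 0.040),
        "S": (-0.45, 0.070, 0.035),
        "T": (-0.35, 0.32, 0.070),
    },
    "S": {
        "P": (0.05, -0.16, 0.020),
        "Q": (-0.12, -0.035, 0.010),
        "R": (0.95, 0.0, 0.012),
        "S": (-0.22, 0.035, 0.010),
        "T": (0.28, 0.29, 0.055),
    },
    "F": {
        "P": (0.06, -0.20, 0.025),
        "Q": (-0.12, -0.048, 0.020),
        "R": (0.95, 0.0, 0.026),
        "S": (-0.35, 0.052, 0.022),
        "T": (-0.05, 0.31, 0.065),
    },
    "Q": {
        "P": (0.04, -0.18, 0.030),
        "Q": (-0.08, -0.050, 0.025),
        "R": (0.50, 0.0, 0.030),
        "S": (-0.15, 0.060, 0.030),
        "T": (0.10, 0.30, 0.070),
    },
}

# Rhythm-level presets for PhysioNet-2017-style record classification.  Each
# preset overrides generator parameters for the whole record: "AF" has an
# irregular rhythm with absent P waves, "O" (other rhythm) is a fast rhythm
# with frequent ectopic beats, "~" (noisy) is a normal rhythm drowned in noise.
RECORD_CLASS_PRESETS: dict[str, dict] = {
    "N": {},
    "AF": {"heart_rate_jitter": 0.25, "beat_class": "S", "heart_rate_mean": 95.0},
    "O": {"heart_rate_mean": 100.0, "class_mix": {"N": 0.7, "V": 0.3}},
    "~": {"noise_scale": 6.0, "baseline_scale": 3.0},
}

# Template support half-width in seconds; bumps are negligible outside this.
_SUPPORT_S = 0.6


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings for one synthetic record.

    Defaults emulate an MIT-BIH-style lead-II recording: 360 samples/s,
    mostly normal beats with a 10% ventricular-ectopic admixture, mild
    additive noise, 0.2 Hz baseline wander and 50 Hz powerline pickup.
    """

    sampling_rate: float = 360.0
    duration: float = 60.0
    heart_rate_mean: float = 75.0
    heart_rate_jitter: float = 0.05
    class_mix: dict[str, float] = field(default_factory=lambda: {"N": 0.9, "V": 0.1})
    noise_sd: float = 0.05
    baseline_wander_amplitude: float = 0.10
    baseline_wander_freq: float = 0.2
    powerline_amplitude: float = 0.02
    powerline_freq: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.heart_rate_mean <= 0:
            raise ValueError("heart_rate_mean must be positive")
        if not self.class_mix:
            raise ValueError("class_mix must be non-empty")
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"class_mix probabilities must sum to 1, got {total}")
        known = set(BEAT_TEMPLATES) | set(RECORD_CLASS_PRESETS)
        unknown = set(self.class_mix) - known
        if unknown:
            raise ValueError(f"unknown classes in class_mix: {sorted(unknown)}")


@dataclass
class ECGRecord:
    """A sampled single-lead waveform with R-peak annotations and labels.

    Exactly one of ``beat_labels`` (one class symbol per R peak) and
    ``record_label`` (one symbol for the whole record) may be absent.
    """

    record_id: str
    signal: np.ndarray
    sampling_rate: float
    rpeak_indices: np.ndarray
    beat_labels: list[str] | None = None
    record_label: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.rpeak_indices = np.asarray(self.rpeak_indices, dtype=int)
        if self.signal.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if self.rpeak_indices.size:
            if np.any(np.diff(self.rpeak_indices) <= 0):
                raise ValueError("rpeak_indices must be strictly increasing")
            if self.rpeak_indices[0] < 0 or self.rpeak_indices[-1] >= self.signal.size:
                raise ValueError(
                    f"record {self.record_id!r}: rpeak index out of signal range"
                )
        if self.beat_labels is None and self.record_label is None:
            raise ValueError("one of beat_labels / record_label is required")
        if self.beat_labels is not None and len(self.beat_labels) != self.rpeak_indices.size:
            raise ValueError("beat_labels length must match rpeak_indices")

    @property
    def n_samples(self) -> int:
        return int(self.signal.size)


def beat_template(
    t: np.ndarray, beat_class: str, p_scale: float = 1.0
) -> np.ndarray:
    """Evaluate the clean template of one beat at times ``t`` (s, R at 0)."""
    waves = BEAT_TEMPLATES[beat_class]
    out = np.zeros_like(np.asarray(t, dtype=float))
    for wave, (amp, mu, sd) in waves.items():
        if wave == "P":
            amp = amp * p_scale
        if amp != 0.0:
            out += amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    return out


def _rpeak_times(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    rr_nominal = 60.0 / config.heart_rate_mean
    times = []
    t = rr_nominal  # leave room for the first P wave
    while t < config.duration:
        times.append(t)
        z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        factor = max(1.0 + config.heart_rate_jitter * z, 0.1)
        t += rr_nominal * factor
    return np.asarray(times)


def clean_signal(
    n_samples: int,
    sampling_rate: float,
    rpeak_times: np.ndarray,
    beat_classes: list[str],
    p_scale: float = 1.0,
) -> np.ndarray:
    """Superpose per-beat templates onto a zero baseline."""
    sig = np.zeros(n_samples)
    half = int(round(_SUPPORT_S * sampling_rate))
    grid = np.arange(n_samples) / sampling_rate
    for t_r, cls in zip(rpeak_times, beat_classes):
        centre = int(round(t_r * sampling_rate))
        lo = max(0, centre - half)
        hi = min(n_samples, centre + half + 1)
        sig[lo:hi] += beat_template(grid[lo:hi] - t_r, cls, p_scale=p_scale)
    return sig


def generate_record(
    config: SynthConfig,
    record_id: str = "synth-0",
    record_label: str | None = None,
) -> ECGRecord:
    """Generate one synthetic record; deterministic given ``config.seed``.

    With ``record_label`` set, a rhythm-level preset from
    :data:`RECORD_CLASS_PRESETS` is applied and the returned record carries a
    record-level label (PhysioNet-2017-style task) instead of beat labels.
    """
    p_scale = 1.0
    noise_scale = 1.0
    baseline_scale = 1.0
    forced_class: str | None = None
    if record_label is not None:
        preset = RECORD_CLASS_PRESETS.get(record_label, {})
        overrides = {
            k: v
            for k, v in preset.items()
            if k in {f.name for f in dataclasses.fields(SynthConfig)}
        }
        if overrides:
            config = dataclasses.replace(config, **overrides)
        noise_scale = preset.get("noise_scale", 1.0)
        baseline_scale = preset.get("baseline_scale", 1.0)
        forced_class = preset.get("beat_class")
        if record_label == "AF":
            p_scale = 0.0  # absent P waves

    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sampling_rate))
    rpeak_times = _rpeak_times(config, rng)
    if rpeak_times.size < 1:
        raise ValueError("record too short: duration admits no complete beat")

    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    beat_classes = [str(c) for c in rng.choice(classes, size=rpeak_times.size, p=probs)]
    if forced_class is not None:
        beat_classes = [forced_class] * rpeak_times.size

    clean = clean_signal(n, config.sampling_rate, rpeak_times, beat_classes, p_scale)
    sig = clean

    grid = np.arange(n) / config.sampling_rate
    if config.noise_sd > 0:
        sig = sig + rng.normal(0.0, config.noise_sd * noise_scale, size=n)
    if config.baseline_wander_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig = sig + (config.baseline_wander_amplitude * baseline_scale) * np.sin(
            2 * np.pi * config.baseline_wander_freq * grid + phase
        )
    if config.powerline_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig = sig + config.powerline_amplitude * np.sin(
            2 * np.pi * config.powerline_freq * grid + phase
        )

    # snap annotations to the clean-template apex so the R-peak index is an
    # exact local argmax (rounding t*fs alone can be one sample off)
    rpeaks = np.round(rpeak_times * config.sampling_rate).astype(int)
    for j, p in enumerate(rpeaks):
        lo, hi = max(0, p - 3), min(n, p + 4)
        if hi > lo:
            rpeaks[j] = lo + int(np.argmax(clean[lo:hi]))
    keep = rpeaks < n
    rpeaks = rpeaks[keep]
    beat_classes = [c for c, k in zip(beat_classes, keep) if k]

    return ECGRecord(
        record_id=record_id,
        signal=sig,
        sampling_rate=config.sampling_rate,
        rpeak_indices=rpeaks,
        beat_labels=None if record_label is not None else beat_classes,
        record_label=record_label,
    )


def _child_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def generate_dataset(
    config: SynthConfig,
    n_records: int,
    task: str = "beat",
) -> list[ECGRecord]:
    """Generate ``n_records`` records with distinct ids and derived seeds.

    ``task="beat"`` yields beat-labelled records; ``task="record"`` draws one
    record-level class per record from ``config.class_mix`` (whose keys must
    then be rhythm classes, e.g. ``{"N": .5, "AF": .3, "~": .2}``).
    """
    if n_records < 1:
        raise ValueError("n_records must be at least 1")
    if task not in {"beat", "record"}:
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(_child_seed(config.seed, 10**6))
    records = []
    for i in range(n_records):
        sub = dataclasses.replace(config, seed=_child_seed(config.seed, i))
        label = None
        if task == "record":
            classes = list(config.class_mix)
            probs = np.array([config.class_mix[c] for c in classes])
            label = str(rng.choice(classes, p=probs))
            # rhythm presets carry their own class_mix; restore a beat-level mix
            sub = dataclasses.replace(sub, class_mix={"N": 1.0})
        records.append(generate_record(sub, record_id=f"synth-{i}", record_label=label))
    return records


def noise_sd_for_snr(config: SynthConfig, snr_db: float) -> float:
    """Noise standard deviation giving the requested SNR against the clean
    template sum for this configuration (SNR = 10 log10(P_signal / sd^2))."""
    clean_cfg = dataclasses.replace(
        config, noise_sd=0.0, baseline_wander_amplitude=0.0, powerline_amplitude=0.0
    )
    rec = generate_record(clean_cfg)
    power = float(np.mean(rec.signal**2))
    return float(np.sqrt(power / (10.0 ** (snr_db / 10.0))))
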