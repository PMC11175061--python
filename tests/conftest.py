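"""Shared fixtures: synthetic records and segment datasets.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from spikecg import SynthConfig, generate_record
from spikecg.synth import noise_sd_for_snr


@pytest.fixture(scope="session")
def clean_config() -> SynthConfig:
    """60 s, 75 bpm, no noise of any kind, N/V mix."""
    return SynthConfig(
        seed=2,
        noise_sd=0.0,
        baseline_wander_amplitude=0.0,
        powerline_amplitude=0.0,
    )


@pytest.fixture(scope="session")
def clean_record(clean_config):
    return generate_record(clean_config)


@pytest.fixture(scope="session")
def snr10_pair(clean_config):
    """(clean signal, noisy signal) at 10 dB SNR with seeded white noise."""
    clean = generate_record(clean_config).signal
    sd = noise_sd_for_snr(clean_config, 10.0)
    noisy = clean + np.random.default_rng(0).normal(0.0, sd, clean.size)
    return clean, noisy


@pytest.fixture(scope="session")
def two_class_config() -> SynthConfig:
    """Balanced N-vs-V generator used for classifier checks."""
    base = SynthConfig(
        seed=7,
        duration=60.0,
        class_mix={"N": 0.5, "V": 0.5},
        noise_sd=0.0,
        baseline_wander_amplitude=0.0,
        powerline_amplitude=0.0,
    )
    return dataclasses.replace(base, noise_sd=noise_sd_for_snr(base, 10.0))
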