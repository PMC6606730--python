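"""Shared fixtures: small simulated sessions and a full-size fixed-seed
session reused by the slower end-to-end tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from emofuse.containers import feature_table
from emofuse.eeg_features import trial_eeg_features
from emofuse.eye_features import assemble_eye_vector
from emofuse.preprocess import fir_bandpass, frame_block
from emofuse.simulate import SimConfig, simulate_dataset

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def short_cfg() -> SimConfig:
    """Cheap conditions for structural tests: full montage, short trials."""
    return SimConfig(n_trials_per_level=2, trial_duration_s=10.0, seed=11)


@pytest.fixture(scope="session")
def full_session():
    """Fixed-seed 200-trial session (40 per level, default 55 s trials) with
    extracted per-trial EEG and eye feature tables."""
    cfg = SimConfig(n_trials_per_level=40, seed=42)
    ds = simulate_dataset(cfg)
    eeg = feature_table(
        [trial_eeg_features(frame_block(fir_bandpass(t))) for t in ds.eeg_trials]
    )
    eye = feature_table([assemble_eye_vector(r) for r in ds.eye_records])
    return ds, {"eeg": eeg, "eye": eye}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
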