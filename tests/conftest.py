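"""Shared fixtures: expensive synthetic datasets and pipeline runs are
session-scoped so unit and acceptance tests reuse them."""

import numpy as np
import pytest

from imusep.pipeline import run_study
from imusep.synthetic import SyntheticConfig, generate_dataset


def clean_config(**kw) -> SyntheticConfig:
    """Study conditions with every injected error switched off."""
    base = dict(
        sta_gain=0.0,
        impact_amplitude_deg=0.0,
        gyro_noise=0.0,
        accel_noise=0.0,
        mag_noise=0.0,
        gyro_bias_sigma=0.0,
        mounting_error_deg=0.0,
        marker_noise_mm=0.0,
        seed=1,
    )
    base.update(kw)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def null_dataset():
    """Zero-error dataset whose movement trial is the static-pose limit of
    the squat (no linear acceleration, so only composition errors remain)."""
    return generate_dataset(clean_config(), 1, 1, trials={"squat": ("squat", 0.0)})


@pytest.fixture(scope="session")
def null_results(null_dataset):
    df, summary, results = run_study(null_dataset)
    return df


@pytest.fixture(scope="session")
def study_squat_dataset():
    """One subject, one full-intensity squat under the standing study
    conditions (STA, impacts, sensor noise, bias, 15 deg frame error)."""
    return generate_dataset(SyntheticConfig(seed=11), 1, 1, trials={"squat": ("squat", 1.0)})


@pytest.fixture(scope="session")
def study_squat_results(study_squat_dataset):
    df, summary, results = run_study(study_squat_dataset)
    return df
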