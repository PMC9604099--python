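"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pandas as pd
import pytest

from clonetrack.simulate import (IntensityNoise, SimConfig, cohort_frame,
                                 simulate_cohort)


@pytest.fixture(scope="session")
def zero_noise_config() -> SimConfig:
    """Default cohort with deterministic intensities (no read noise)."""
    return SimConfig(
        seed=11,
        intensity_noise=IntensityNoise(background_sd=0.0, signal_sd=0.0))


@pytest.fixture(scope="session")
def zero_noise_cohort(zero_noise_config):
    embryos, truth = simulate_cohort(zero_noise_config)
    return embryos, truth


@pytest.fixture(scope="session")
def zero_noise_cells(zero_noise_cohort) -> pd.DataFrame:
    embryos, _ = zero_noise_cohort
    return cohort_frame(embryos)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-condition cohort with realistic intensity noise."""
    embryos, truth = simulate_cohort(SimConfig(seed=5))
    return embryos, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
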