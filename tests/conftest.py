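import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import exofatigue as xf

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def subject_f() -> xf.SubjectProfile:
    """Cohort-mean female participant."""
    return xf.SubjectProfile("F01", "female", 24.0, 59.0, 1.65, "right", 3.0)


@pytest.fixture(scope="session")
def subject_m() -> xf.SubjectProfile:
    """Cohort-mean male participant."""
    return xf.SubjectProfile("M01", "male", 27.0, 74.0, 1.78, "right", 1.0)


@pytest.fixture(scope="session")
def mtg_m(subject_m) -> xf.MtgModel:
    return xf.scale_model(subject_m)


@pytest.fixture(scope="session")
def fast_trial_config() -> xf.TrialConfig:
    """Reduced EMG rate/band for quick unit tests (synthesis cost scales
    with the sample rate; the science under test does not)."""
    return xf.TrialConfig(sample_rate_emg=1000.0, emg_band_hz=(20.0, 400.0))


@pytest.fixture(scope="session")
def small_table() -> xf.MeasureTable:
    """Small end-to-end cohort table shared by evaluation/stats tests."""
    return xf.run_pipeline(
        xf.CohortConfig(n_per_sex=2),
        xf.TrialConfig(sample_rate_emg=1000.0, emg_band_hz=(20.0, 400.0)),
        seed=3,
    )
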