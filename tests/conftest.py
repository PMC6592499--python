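import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppgaf.core import WindowSample
from ppgaf.preprocess import segment
from ppgaf.simulate import CohortConfig, RhythmParams, generate_cohort, simulate_record

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """12 patients, 4-minute recordings: fast but structurally complete."""
    return generate_cohort(12, CohortConfig(duration=240), seed=11)


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    return [w for rec in small_cohort for w in segment(rec)]


@pytest.fixture(scope="session")
def clean_sr_window():
    """Noise-free SR window with constant 1.0-s intervals."""
    params = RhythmParams(
        rhythm="SR", mean_rr=1.0, rr_sd=0.0, resp_mod_depth=0.0,
        noise_sd=0.0, duration=60.0, seed=1,
    )
    rec = simulate_record(params)
    return segment(rec)[0], rec


@pytest.fixture()
def noise_window():
    rng = np.random.default_rng(0)
    x = rng.normal(size=3000)
    return WindowSample(
        samples=(x - x.mean()) / x.std(), fs=100.0, start_time=0.0,
        label="SR", patient_id="PX", window_index=0,
    )
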