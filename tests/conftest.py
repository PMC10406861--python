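import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nucswap.simulate import TimeCourseDesign, TraceSimulationParams

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def default_params():
    return TraceSimulationParams()


@pytest.fixture
def ideal_params():
    """Zero noise, no photobleaching: traces round-trip exactly."""
    return TraceSimulationParams().without_corruptions()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_design():
    return TimeCourseDesign(
        time_points_h=(0, 2, 8, 24), n_molecules_per_replicate=25,
        n_replicates=2, seed=7,
    )


@pytest.fixture(scope="session")
def default_pipeline_report():
    """One full-scale end-to-end run shared by the expensive checks."""
    from nucswap.pipeline import RunConfig, run_pipeline

    cfg = RunConfig(scenario="unmod_low_salt", design=TimeCourseDesign(seed=0))
    return run_pipeline(cfg)
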