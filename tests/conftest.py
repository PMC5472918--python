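import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from voc_ethogram import Arena, SimulationConfig, default_presets, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def arena():
    return Arena()


@pytest.fixture(scope="session")
def small_trackset():
    """Two groups x two individuals x 60 s -- enough for I/O and plumbing tests."""
    presets = default_presets()
    cfg = SimulationConfig(duration=60.0, n_individuals=2, seed=11)
    keys = [("wild_type", "control"), ("p53", "formaldehyde")]
    return generate_cohort({k: presets[k] for k in keys}, cfg, session="post")


@pytest.fixture(scope="session")
def wt_control_tracks():
    """Wild-type control cohort, 6 tracks x 5 min, for mid-sized analyses."""
    presets = default_presets()
    cfg = SimulationConfig(duration=300.0, n_individuals=6, seed=7)
    return generate_cohort({("wild_type", "control"): presets[("wild_type", "control")]}, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
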