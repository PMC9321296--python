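import warnings

import pytest
from hypothesis import HealthCheck, settings

from edcast.framing import FramingConfig, build_left_aligned, chronological_split
from edcast.simulate import SimConfig, simulate_stream

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# lifelines/our fitters warn about intentionally dropped covariates on short horizons
warnings.filterwarnings("ignore", message="dropping constant or collinear covariates")


@pytest.fixture(scope="session")
def small_stream():
    """30 simulated days, ~4300 visits; cheap shared fixture."""
    return simulate_stream(SimConfig(horizon_days=30, seed=1))


@pytest.fixture(scope="session")
def default_stream():
    """The reference study conditions: 140 days, ~20k visits."""
    return simulate_stream(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_split(default_stream):
    return chronological_split(default_stream, FramingConfig().split_fractions)


@pytest.fixture(scope="session")
def default_bundle(default_stream, default_split):
    """Per-cutoff classifiers trained on the training days of the reference stream."""
    from edcast.classifiers import train_bundle

    fc = FramingConfig()
    train, _, _ = default_split.assign(default_stream)
    rows = {c: build_left_aligned(train, c, fc) for c in fc.cutoffs_minutes}
    return train_bundle(rows)
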