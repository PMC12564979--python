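import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_heatmap_params():
    """A 64x64 toy grid small enough for brute-force entropy oracles."""
    from gazentropy import HeatmapParams

    return HeatmapParams(sigma_px=6.0, grid_w=64, grid_h=64)


@pytest.fixture(scope="session")
def default_curve():
    """Calibration curve for the full-resolution default grid (cached)."""
    from gazentropy import HeatmapParams, calibrate_entropy_control

    return calibrate_entropy_control(HeatmapParams(), rng=0)
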