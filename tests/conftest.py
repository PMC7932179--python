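import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from hdcmetrics.geometry import Plane, build_fistula_frame, fit_plane
from hdcmetrics.synthetic import TrialConfig, generate_trial

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def skin_plane():
    """Horizontal skin plane z = 0 with upward normal."""
    return Plane(np.array([0.0, 0.0, 1.0]), 0.0)


@pytest.fixture(scope="session")
def axis_frame():
    """Fistula frame with axis along +X in the plane z = 0, radius 7 mm."""
    vertices = np.array(
        [[-75.0, -7.0, 0.0], [75.0, -7.0, 0.0], [75.0, 7.0, 0.0], [-75.0, 7.0, 0.0]]
    )
    return build_fistula_frame(vertices, radius=7.0)


@pytest.fixture(scope="session")
def noiseless_trial():
    """Default synthetic trial with the sensor noise switched off."""
    return generate_trial(TrialConfig(noise_sd_mm=0.0))


@pytest.fixture(scope="session")
def noisy_trial():
    return generate_trial(TrialConfig(seed=7))


def make_straight_config(alpha_deg, **overrides):
    """Config whose entire tip path is one straight line at ``alpha_deg``."""
    defaults = dict(
        alpha1_deg=alpha_deg,
        alpha3_deg=alpha_deg,
        level_out=False,
        advance3_mm=3.0,
        noise_sd_mm=0.0,
        n_retractions=0,
        phase1_s=1.6,
        phase3_s=1.2,
        rotation_pause_s=0.4,
        pre_roll_s=0.2,
        post_roll_s=0.2,
    )
    defaults.update(overrides)
    return TrialConfig(**defaults)
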