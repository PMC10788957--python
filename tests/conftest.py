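import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import curvsense as cs

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    """Default buckled geometry: 20x10 nm box, A=2 nm, t=2 nm."""
    return cs.BuckleGeometry()


@pytest.fixture(scope="session")
def flat_geometry():
    return cs.BuckleGeometry(amplitude=0.0)


@pytest.fixture(scope="session")
def sine_beads():
    """10^3 noiseless beads on z = 2 sin(2 pi x / 20) in a 20x10 box."""
    rng = np.random.default_rng(42)
    x = rng.random(1000) * 20.0
    y = rng.random(1000) * 10.0
    z = 2.0 * np.sin(2.0 * np.pi * x / 20.0)
    return np.column_stack([x, y, z])


@pytest.fixture(scope="session")
def upper_parallel_surface(geometry):
    """Noiseless fit of the upper-leaflet parallel surface (A=2, t=2)."""
    from curvsense.sampling import fit_frame_surfaces

    frame = cs.generate_frame(geometry, 0.0, seed=0)
    return fit_frame_surfaces(frame, (6, 1))["upper"]
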