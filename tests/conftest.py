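import numpy as np
import pytest
from hypothesis import settings

from hemoeit import Scenario, simulate
from hemoeit.mesh import build_circular_mesh, make_protocol
from hemoeit.pipeline import analyze_frames
from hemoeit.reconstruct import build_b, compute_sensitivity

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=25)
settings.load_profile("suite")

RADIUS = 0.10


@pytest.fixture(scope="session")
def protocol():
    return make_protocol()


@pytest.fixture(scope="session")
def forward_mesh():
    """Generator mesh, ~4x finer than the inverse mesh (no inverse crime)."""
    return build_circular_mesh(RADIUS, 1600)


@pytest.fixture(scope="session")
def inverse_mesh():
    return build_circular_mesh(RADIUS, 400)


@pytest.fixture(scope="session")
def coarse_mesh():
    """Small mesh for brute-force oracle checks."""
    return build_circular_mesh(RADIUS, 150)


@pytest.fixture(scope="session")
def sensitivity(inverse_mesh, protocol):
    return compute_sensitivity(inverse_mesh, protocol, 0.3)


@pytest.fixture(scope="session")
def recon(sensitivity):
    return build_b(sensitivity)


@pytest.fixture(scope="session")
def full_frames(forward_mesh, protocol):
    """Default 5 min baseline + 6 min injection scenario at 2 frames/s."""
    scenario = Scenario(frame_rate_hz=2.0, seed=11)
    return simulate(scenario, forward_mesh, protocol)


@pytest.fixture(scope="session")
def full_analysis(full_frames, inverse_mesh, recon):
    return analyze_frames(full_frames, inverse_mesh, recon=recon)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
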