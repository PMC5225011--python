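import numpy as np
import pytest

from lumenwall.geometry import Ellipse, Frame
from lumenwall.phantom import PhantomSpec, generate_phantom
from lumenwall.tracker import ParticleState, TrackerConfig
from lumenwall.volume import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ring_volume(radius=10.0, wall=100.0, lumen=0.0, half=16, spacing=1.0,
                     thickness=3.0, background=0.0):
    """Axis-aligned circular-cylinder wall around the z axis, centred at 0."""
    n = 2 * half + 1
    ax = (np.arange(n) - half) * spacing
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    rho = np.sqrt(xx**2 + yy**2)
    sl = np.where((rho >= radius) & (rho < radius + thickness), wall,
                  np.where(rho < radius, lumen, background))
    data = np.repeat(sl[:, :, None], n, axis=2)
    return Volume(data, [spacing] * 3, [-half * spacing] * 3, np.eye(3))


@pytest.fixture
def ring_volume():
    return make_ring_volume()


@pytest.fixture
def straight_phantom():
    spec = PhantomSpec(shape="straight", length_mm=60, inner_radius_mm=8,
                       wall_thickness_mm=3)
    return generate_phantom(spec)


@pytest.fixture
def seed_state():
    return ParticleState(c=[0.0, 0.0, 5.0], R=Frame.identity(),
                         e=Ellipse(8.0, 8.0, 0.0), q=1.0)


@pytest.fixture
def small_tracker_config():
    return TrackerConfig(Ns=80, T_max=80)
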