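import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spheretect as sp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def geom():
    """Default embryo geometry: centre at origin, anterior = +z, dorsal = +x."""
    return sp.EmbryoGeometry(center=np.zeros(3), radius_R=350.0,
                             anterior_axis=(0.0, 0.0, 1.0), dorsal_ref=(1.0, 0.0, 0.0))


@pytest.fixture
def tilted_geom():
    """Off-centre embryo with oblique anatomical axes (exercises the general path)."""
    return sp.EmbryoGeometry(center=(12.0, -7.0, 30.0), radius_R=340.0,
                             anterior_axis=(0.3, -0.1, 0.94), dorsal_ref=(0.9, 0.2, 0.1))


@pytest.fixture(scope="session")
def mesh500():
    return sp.make_mesh(500)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def shell_points(rng, n, geom, thickness=30.0):
    """Uniform random points on the embryo shell (helper, not a fixture)."""
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.uniform(geom.radius_R - thickness / 2, geom.radius_R + thickness / 2, n)
    return geom.center + u * r[:, None]
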