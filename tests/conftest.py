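import numpy as np
import pytest

from insideoutside import PointCloud, ShapeSpec, make_test_shape


@pytest.fixture
def tetrahedron():
    """Regular tetrahedron inscribed in the unit sphere."""
    c = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    return PointCloud(c / np.sqrt(3))


@pytest.fixture
def unit_cube():
    c = np.array([[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)])
    return PointCloud(c)


@pytest.fixture
def sphere_cloud():
    """100 uniform random points on the unit sphere (fixed seed)."""
    rng = np.random.default_rng(11)
    g = rng.standard_normal((100, 3))
    return PointCloud(g / np.linalg.norm(g, axis=1, keepdims=True))


@pytest.fixture
def blastocyst_shape():
    """Default simulated shape: 100 sphere + 50 ball points, easy inner radius."""
    return make_test_shape(ShapeSpec(inner_radius=0.1, rng_seed=42))


@pytest.fixture
def random_rigid_motion():
    """A fixed random rotation matrix and translation vector."""
    rng = np.random.default_rng(7)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.standard_normal(3) * 10.0
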