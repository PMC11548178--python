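import numpy as np
import pytest

from geoclique.bodymodel import make_toy_humanoid
from geoclique.mesh import TriangleMesh


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_humanoid()


def grid_mesh(n: int = 11, extent: float = 1.0, heights=None) -> TriangleMesh:
    """Regular triangulated grid on [0, extent]^2, optionally displaced in z."""
    xs = np.linspace(0.0, extent, n)
    X, Y = np.meshgrid(xs, xs)
    Z = np.zeros_like(X) if heights is None else heights
    V = np.stack([X.ravel(), Y.ravel(), np.asarray(Z).ravel()], axis=1)
    F = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            F.append([a, b, d])
            F.append([a, d, c])
    return TriangleMesh(V, np.array(F))


def bumpy_mesh(n: int = 18, seed: int = 0, amp: float = 0.08) -> TriangleMesh:
    """Random smooth heightfield; asymmetric enough for descriptor tests."""
    rng = np.random.default_rng(seed)
    coarse = rng.normal(size=(4, 4))
    xs = np.linspace(0, 3, n)
    from scipy.interpolate import RectBivariateSpline

    spline = RectBivariateSpline(np.arange(4), np.arange(4), coarse, kx=3, ky=3)
    Z = amp * spline(xs, xs)
    return grid_mesh(n=n, extent=1.0, heights=Z)


def icosphere_mesh(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.array(ico.vertices), np.array(ico.faces))


@pytest.fixture
def flat_grid():
    return grid_mesh()


@pytest.fixture
def icosphere():
    return icosphere_mesh()
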