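import numpy as np
import pytest

from archkit.synth import build_chain, make_module, synth_noe


@pytest.fixture(scope="session")
def module_pair():
    """Two default pseudo-modules with distinct internal windings."""
    return make_module(seed=1, name="A"), make_module(seed=2, name="B")


@pytest.fixture(scope="session")
def chain118(module_pair):
    """Compact two-module chain at the bent junction geometry (tilt 118)."""
    m1, m2 = module_pair
    return build_chain([m1, m2], [(118.0, 57.0, 89.0, 6)], seed=0)


@pytest.fixture(scope="session")
def noe118(chain118):
    chain, arch = chain118
    return synth_noe(chain, arch, include_intra=False)


@pytest.fixture(scope="session")
def sphere_points():
    """5000 points uniform in a sphere of radius 30 A (3 nm)."""
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(12000, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= (rng.random(12000) ** (1.0 / 3.0))[:, None] * 30.0
    return pts[:5000]


def sphere_form_factor(x: np.ndarray) -> np.ndarray:
    """Normalized intensity of a uniform sphere, x = s R."""
    amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    return amp**2


def sphere_grid_fill(radius_a: float = 30.0, n_target: int = 5000) -> np.ndarray:
    """Deterministic cubic-grid fill of a sphere with ~n_target points (A)."""
    h = (4.0 / 3.0 * np.pi * radius_a**3 / n_target) ** (1.0 / 3.0)
    g = np.arange(-radius_a, radius_a + 1e-9, h)
    X, Y, Z = np.meshgrid(g, g, g)
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return pts[np.linalg.norm(pts, axis=1) <= radius_a]
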