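import numpy as np
import pytest

from memchiral.descriptors import PointCloud
from memchiral.synthetic_structures import SyntheticSpec, generate


@pytest.fixture
def cube_corners() -> PointCloud:
    pts = np.array([[x, y, z] for x in (-1.0, 1.0) for y in (-1.0, 1.0)
                    for z in (-1.0, 1.0)])
    return PointCloud(pts)


@pytest.fixture
def helix_model():
    """500-atom right-handed helix, radius 2 A, pitch 5 A, 10 turns."""
    return generate(SyntheticSpec(preset="helix", n_atoms=500, seed=3,
                                  helix_radius=2.0, helix_pitch=5.0,
                                  turns=10.0))


@pytest.fixture
def bilayer_model():
    """Bilayer patch: leaflet P planes at +/-19 A, 0.3 A placement noise."""
    return generate(SyntheticSpec(preset="bilayer", seed=5, noise_sd=0.3,
                                  leaflet_z=19.0, n_popc=70, n_pope=50,
                                  n_chl=0, n_proteins=3))


def random_cloud(n: int, seed: int, sds=(3.0, 2.0, 1.0)) -> PointCloud:
    """Anisotropic Gaussian cloud with distinct principal axes."""
    rng = np.random.default_rng(seed)
    return PointCloud(rng.normal(size=(n, 3)) * np.asarray(sds))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def uniform_ball(n: int, rng: np.random.Generator,
                 radius: float = 10.0) -> np.ndarray:
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    return radius * pts * rng.uniform(0.0, 1.0, n)[:, None] ** (1.0 / 3.0)
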