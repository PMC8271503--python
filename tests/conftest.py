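import numpy as np
import pytest

from sdmon.geometry import Homography


def random_homography(rng: np.random.Generator) -> Homography:
    """A random well-conditioned projective map.

    Affine part: rotation x anisotropic scale in [0.5, 2] plus translation;
    perspective row small enough that points in [-5, 5]^2 stay far from the
    horizon line.
    """
    theta = rng.uniform(0.0, 2.0 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    scale = rng.uniform(0.5, 2.0, size=2)
    a = np.array([[c, -s], [s, c]]) @ np.diag(scale)
    t = rng.uniform(-10.0, 10.0, size=2)
    persp = rng.uniform(-0.01, 0.01, size=2)
    m = np.eye(3)
    m[:2, :2] = a
    m[:2, 2] = t
    m[2, :2] = persp
    return Homography(m)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
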