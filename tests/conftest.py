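import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20140999)


@pytest.fixture
def points(rng):
    """Random sample points away from the pole (field symmetries are exact
    only where the polar angle is defined)."""
    pts = rng.uniform(-300.0, 300.0, size=(1000, 2))
    r = np.hypot(pts[:, 0], pts[:, 1])
    return pts[r > 1.0]


def rotation_matrix(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s], [s, c]])
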