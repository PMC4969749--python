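import numpy as np
import pytest

from neurostrain import Curve3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_z_curve():
    """Straight 11-point segment from origin to (0, 0, 10) µm."""
    return Curve3D(np.column_stack([np.zeros(11), np.zeros(11), np.linspace(0, 10, 11)]))


def semicircle_curve(radius=10.0, n=2001):
    """Semicircular arc of given radius in the x1–x3 plane."""
    theta = np.linspace(0.0, np.pi, n)
    pts = np.column_stack(
        [radius * np.cos(theta), np.zeros_like(theta), radius * np.sin(theta)]
    )
    return Curve3D(pts)


def random_symmetric_tensor(rng, scale=0.3):
    A = rng.normal(scale=scale, size=(3, 3))
    return 0.5 * (A + A.T)
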