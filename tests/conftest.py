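"""Shared fixtures: deterministic smooth images and velocity fields."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from pdereg.grid import GridSpec, ScalarField, VectorField


def _smooth_image(grid: GridSpec, seed: int, lo: float, hi: float, sig: float) -> ScalarField:
    rng = np.random.default_rng(seed)
    a = gaussian_filter(rng.standard_normal(grid.shape), sig, mode="wrap")
    a = (a - a.min()) / (a.max() - a.min())
    return ScalarField(grid, lo + a * (hi - lo))


def _smooth_velocity(grid: GridSpec, seed: int, amp: float, sig: float) -> VectorField:
    rng = np.random.default_rng(seed)
    w = gaussian_filter(
        rng.standard_normal((grid.dim,) + grid.shape),
        (0,) + (sig,) * grid.dim,
        mode="wrap",
    )
    return VectorField(grid, w * (amp / np.abs(w).max()))


@pytest.fixture(scope="session")
def smooth_image():
    return _smooth_image


@pytest.fixture(scope="session")
def smooth_velocity():
    return _smooth_velocity


@pytest.fixture(scope="session")
def grid64():
    return GridSpec((64, 64))


@pytest.fixture(scope="session")
def grid32():
    return GridSpec((32, 32))


@pytest.fixture(scope="session")
def blob_pair():
    """Default synthetic study pair: 64^2 blob template warped by a smooth
    band-limited diffeomorphism with ~6 voxel maximum displacement."""
    from pdereg.synth import FixtureSpec, make_pair

    return make_pair(FixtureSpec(seed=3))
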