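"""Synthetic ground-truth generator.

Produces image pairs related by a known smooth diffeomorphism: a labeled
template, a band-limited random velocity field scaled to a target maximum
displacement (validated to keep the Jacobian determinant positive), the warped
image with optional monotone intensity remapping to emulate a second modality,
and optional additive Gaussian noise.  Everything is deterministic in the
seed, so all tests run without external data.

Default study conditions: 64x64 grids, velocities supported on the lowest
eight frequencies per axis, maximum displacement of six voxels, no noise, and
identity modality mapping; the gamma remap (exponent 0.7 on [0,1] intensities)
is the pseudo-multimodal setting used by the multimodal experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .grid import GridSpec, ScalarField, VectorField, include_band, project_band
from .transport import TimeGrid, cgl_nodes, interp_prefiltered_cubic, solve_deformation, solve_jacobian

__all__ = [
    "FixtureSpec",
    "FixturePair",
    "make_template",
    "sample_velocity",
    "make_pair",
    "scale_intensities",
    "presmooth",
]

TEMPLATES = ("blob", "concentric_rings", "checker_organ")
MODALITY_MAPS = ("identity", "gamma", "inverted", "quantile_remap")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic registration pair."""

    shape: tuple[int, ...] = (64, 64)
    seed: int = 0
    velocity_band: int = 8
    velocity_amplitude: float = 6.0  # max displacement in voxels
    template: str = "blob"
    noise_sd: float = 0.0
    modality_map: str = "identity"
    gamma: float = 0.7

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        if self.modality_map not in MODALITY_MAPS:
            raise ValueError(f"unknown modality map {self.modality_map!r}")


@dataclass
class FixturePair:
    """Source/target images, labels, and the ground-truth transformation."""

    i0: ScalarField
    i1: ScalarField
    labels0: np.ndarray
    labels1: np.ndarray
    v_true: VectorField
    phi_disp_true: VectorField
    psi_disp_true: VectorField
    jac_min: float


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


def make_template(grid: GridSpec, name: str = "blob") -> tuple[np.ndarray, np.ndarray]:
    """Labeled synthetic template; intensities in [0, 1], labels 0..K with
    at least four foreground structures of varying scale."""
    coords = grid.coords()
    r2 = sum((c - 0.5) ** 2 for c in coords)
    r = np.sqrt(r2)
    if name == "blob":
        img = np.exp(-r2 / (2 * 0.16**2))
        img += 0.45 * np.exp(-sum((c - 0.3) ** 2 for c in coords) / (2 * 0.07**2))
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[r < 0.10] = 1
        labels[(r >= 0.10) & (r < 0.18)] = 2
        labels[(r >= 0.18) & (r < 0.26)] = 3
        labels[np.sqrt(sum((c - 0.3) ** 2 for c in coords)) < 0.08] = 4
    elif name == "concentric_rings":
        img = 0.5 + 0.5 * np.cos(2 * np.pi * 5 * r) * np.exp(-r2 / (2 * 0.3**2))
        labels = np.zeros(grid.shape, dtype=np.int32)
        edges = [0.0, 0.08, 0.16, 0.24, 0.32]
        for k in range(4):
            labels[(r >= edges[k]) & (r < edges[k + 1])] = k + 1
    else:  # checker_organ
        organ = sum(((c - 0.5) / w) ** 2 for c, w in zip(coords, (0.33, 0.26, 0.3))) < 1.0
        checker = 0.5 + 0.25 * np.cos(2 * np.pi * 4 * coords[0]) * np.cos(
            2 * np.pi * 4 * coords[1]
        )
        img = np.where(organ, checker + 0.25, 0.05)
        labels = np.zeros(grid.shape, dtype=np.int32)
        quad = (coords[0] >= 0.5).astype(np.int32) * 2 + (coords[1] >= 0.5).astype(np.int32)
        labels[organ] = quad[organ] + 1
        labels[r < 0.08] = 5
    img = ndimage.gaussian_filter(img, sigma=1.5, mode="wrap")
    img = (img - img.min()) / (img.max() - img.min())
    return img, labels


# ---------------------------------------------------------------------------
# velocities
# ---------------------------------------------------------------------------


def sample_velocity(spec: FixtureSpec, grid: Optional[GridSpec] = None) -> VectorField:
    """Random band-limited velocity with max displacement ``velocity_amplitude``
    voxels per unit time; regenerated with reduced amplitude if the induced
    Jacobian determinant is not safely positive."""
    grid = grid if grid is not None else GridSpec(spec.shape)
    if spec.velocity_amplitude == 0.0:
        return VectorField.zeros(grid)
    rng = np.random.default_rng(spec.seed)
    noise = VectorField(grid, rng.standard_normal((grid.dim,) + grid.shape))
    band = tuple(min(spec.velocity_band, n) for n in grid.shape)
    v = include_band(project_band(noise, band), grid)
    amp = spec.velocity_amplitude
    nmax = max(grid.shape)
    tg = cgl_nodes(5)
    for _ in range(6):
        vox = np.sqrt(sum((v.data[a] * grid.shape[a]) ** 2 for a in range(grid.dim)))
        scaled = VectorField(grid, v.data * (amp / vox.max()))
        jmin = float(solve_jacobian(scaled, tg)[0].data.min())
        if jmin > 0.05:
            return scaled
        amp *= 0.8
    raise RuntimeError("could not generate a diffeomorphic velocity; reduce amplitude")


# ---------------------------------------------------------------------------
# pairs
# ---------------------------------------------------------------------------


def _apply_modality(img: np.ndarray, spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = img.min(), img.max()
    u = (img - lo) / max(hi - lo, 1e-12)
    if spec.modality_map == "identity":
        return img
    if spec.modality_map == "gamma":
        return lo + (hi - lo) * u**spec.gamma
    if spec.modality_map == "inverted":
        return lo + (hi - lo) * (1.0 - u)
    # quantile_remap: monotone piecewise-linear remap of the intensity CDF
    knots = np.linspace(0, 1, 6)
    values = np.sort(rng.uniform(0, 1, 6))
    values[0], values[-1] = 0.0, 1.0
    return lo + (hi - lo) * np.interp(u, knots, values)


def make_pair(spec: FixtureSpec) -> FixturePair:
    """Build a synthetic pair: I1 = modality(I0 o phi_true) + noise, with the
    labels pulled through the same ground-truth map."""
    grid = GridSpec(spec.shape)
    img0, labels0 = make_template(grid, spec.template)
    v = sample_velocity(spec, grid)
    tg = cgl_nodes(8)
    phi = solve_deformation(v, tg, "forward", nsub=4)
    psi = solve_deformation(v, tg, "inverse", nsub=4)
    jac = solve_jacobian(v, tg, nsub=4)
    base = grid.index_coords()
    scale = np.asarray(grid.shape, dtype=float).reshape((-1,) + (1,) * grid.dim)
    pts = base + phi[-1].data * scale
    warped = ndimage.map_coordinates(
        ndimage.spline_filter(img0, order=3, mode="grid-wrap"),
        pts, order=3, mode="grid-wrap", prefilter=False,
    )
    labels1 = ndimage.map_coordinates(labels0, pts, order=0, mode="grid-wrap")
    rng = np.random.default_rng(spec.seed + 1)
    i1 = _apply_modality(warped, spec, rng)
    if spec.noise_sd > 0:
        i1 = i1 + rng.normal(0.0, spec.noise_sd, size=i1.shape)
    return FixturePair(
        i0=ScalarField(grid, img0),
        i1=ScalarField(grid, i1),
        labels0=labels0,
        labels1=labels1,
        v_true=v,
        phi_disp_true=phi[-1],
        psi_disp_true=psi[0],
        jac_min=float(jac[0].data.min()),
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def scale_intensities(img: ScalarField, target_range: tuple[float, float]) -> ScalarField:
    """Affine min-max rescale into the metric's expected intensity range."""
    lo, hi = float(img.data.min()), float(img.data.max())
    if hi - lo <= 0:
        raise ValueError("cannot rescale a constant image")
    a, b = target_range
    out = a + (img.data - lo) * ((b - a) / (hi - lo))
    np.clip(out, min(a, b), max(a, b), out=out)
    out[img.data == lo] = a
    out[img.data == hi] = b
    return ScalarField(img.grid, out)


def presmooth(img: ScalarField, sd: float) -> ScalarField:
    """Periodic Gaussian smoothing (in voxels); sd = 0 is the identity."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return img.copy()
    return ScalarField(img.grid, ndimage.gaussian_filter(img.data, sigma=sd, mode="wrap"))
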