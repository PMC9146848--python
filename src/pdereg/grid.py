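"""Regular-grid field types, the Sobolev metric operator, and band-limited algebra.

All fields live on a periodic unit domain [0, 1)^d discretized with voxel
centers at i/N (0-based).  The Riemannian metric on velocity fields is induced
by the invertible self-adjoint operator

    L = (Id - alpha * Laplacian)^s,      K = L^{-1},

applied through its exact spectral symbol.  Band-limited velocity fields are
represented by a centered, conjugate-symmetric box of Fourier-series
coefficients; ``project_band`` / ``include_band`` are mutually adjoint under
the discrete inner products and satisfy ``project_band(include_band(b)) == b``
exactly.

Discrete inner products: spatial fields use the unit-domain integral
(mean over voxels, summed over components); band-limited fields use the plain
l2 product of their complex coefficients, which makes Parseval exact.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "ScalarField",
    "VectorField",
    "BandLimitedField",
    "RegularizerSpec",
    "apply_L",
    "apply_K",
    "apply_L_bl",
    "apply_K_bl",
    "spectral_gradient",
    "spectral_divergence",
    "fd_gradient",
    "fd_divergence",
    "project_band",
    "include_band",
    "truncated_convolution",
    "inner",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular periodic grid over the unit domain.

    ``spacing`` follows the unit-domain convention ``1/shape`` per axis.
    """

    shape: tuple[int, ...]

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (2, 3):
            raise ValueError(f"grid must be 2D or 3D, got shape {shape}")
        if any(n < 4 for n in shape):
            raise ValueError(f"all grid axes must have >= 4 voxels, got {shape}")

    @property
    def dim(self) -> int:
        return len(self.shape)

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(1.0 / n for n in self.shape)

    @property
    def nvox(self) -> int:
        return int(np.prod(self.shape))

    def freqs(self) -> list[np.ndarray]:
        """Integer Fourier frequencies per axis (fftfreq convention)."""
        return [np.fft.fftfreq(n, d=1.0 / n) for n in self.shape]

    def freq_mesh(self) -> list[np.ndarray]:
        return np.meshgrid(*self.freqs(), indexing="ij")

    def coords(self) -> list[np.ndarray]:
        axes = [np.arange(n) / n for n in self.shape]
        return np.meshgrid(*axes, indexing="ij")

    def index_coords(self) -> np.ndarray:
        """(d, *shape) array of voxel index coordinates."""
        return np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in self.shape], indexing="ij"))


def _check_finite(data: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{what} contains non-finite values")


@dataclass
class ScalarField:
    """Scalar quantity sampled on a :class:`GridSpec` (images, adjoints, Jacobians)."""

    grid: GridSpec
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(f"data shape {self.data.shape} != grid shape {self.grid.shape}")

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.data.copy())


@dataclass
class VectorField:
    """d-component field on a :class:`GridSpec` (velocities, displacements, rho)."""

    grid: GridSpec
    data: np.ndarray  # (d, *shape)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.grid.dim,) + self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != {(self.grid.dim,) + self.grid.shape}"
            )

    @classmethod
    def zeros(cls, grid: GridSpec) -> "VectorField":
        return cls(grid, np.zeros((grid.dim,) + grid.shape))

    def copy(self) -> "VectorField":
        return VectorField(self.grid, self.data.copy())

    # vector-space operations used by the optimizers
    def __add__(self, other: "VectorField") -> "VectorField":
        return VectorField(self.grid, self.data + other.data)

    def __sub__(self, other: "VectorField") -> "VectorField":
        return VectorField(self.grid, self.data - other.data)

    def __mul__(self, a: float) -> "VectorField":
        return VectorField(self.grid, self.data * a)

    __rmul__ = __mul__

    def __neg__(self) -> "VectorField":
        return VectorField(self.grid, -self.data)


def _box_halfwidths(bounds: Sequence[int], shape: Sequence[int] | None = None) -> tuple[int, ...]:
    hw = [int(b) // 2 for b in bounds]
    if shape is not None:
        hw = [min(h, n // 2) for h, n in zip(hw, shape)]
    return tuple(hw)


@dataclass
class BandLimitedField:
    """Velocity field represented by a centered box of Fourier-series coefficients.

    ``coeffs`` has shape ``(dim, 2*h1+1, ..., 2*hd+1)`` with per-axis
    half-widths ``h_j`` covering integer frequencies ``-h_j .. h_j``; conjugate
    (Hermitian) symmetry is enforced at construction so every lift to the
    spatial domain is real-valued.
    """

    bounds: tuple[int, ...]
    coeffs: np.ndarray

    def __post_init__(self):
        self.bounds = tuple(int(b) for b in self.bounds)
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        d = self.coeffs.shape[0]
        if d != len(self.bounds):
            raise ValueError("component count must equal len(bounds)")
        self.coeffs = _hermitize(self.coeffs)

    @property
    def dim(self) -> int:
        return self.coeffs.shape[0]

    @property
    def halfwidths(self) -> tuple[int, ...]:
        return tuple((n - 1) // 2 for n in self.coeffs.shape[1:])

    def box_freqs(self) -> list[np.ndarray]:
        return [np.arange(-h, h + 1, dtype=float) for h in self.halfwidths]

    @classmethod
    def zeros(cls, bounds: Sequence[int], shape: Sequence[int] | None = None) -> "BandLimitedField":
        hw = _box_halfwidths(bounds, shape)
        box = tuple(2 * h + 1 for h in hw)
        return cls(tuple(bounds), np.zeros((len(hw),) + box, dtype=complex))

    def copy(self) -> "BandLimitedField":
        return BandLimitedField(self.bounds, self.coeffs.copy())

    def __add__(self, other: "BandLimitedField") -> "BandLimitedField":
        return BandLimitedField(self.bounds, self.coeffs + other.coeffs)

    def __sub__(self, other: "BandLimitedField") -> "BandLimitedField":
        return BandLimitedField(self.bounds, self.coeffs - other.coeffs)

    def __mul__(self, a: float) -> "BandLimitedField":
        return BandLimitedField(self.bounds, self.coeffs * a)

    __rmul__ = __mul__

    def __neg__(self) -> "BandLimitedField":
        return BandLimitedField(self.bounds, -self.coeffs)


def _hermitize(box: np.ndarray) -> np.ndarray:
    """Project a centered coefficient box onto conjugate-symmetric spectra."""
    axes = tuple(range(1, box.ndim))
    flipped = np.flip(box, axis=axes)
    return 0.5 * (box + np.conj(flipped))


@dataclass(frozen=True)
class RegularizerSpec:
    """Parameters of L = (Id - alpha*Laplacian)^s."""

    alpha: float = 0.0025
    s: int = 2

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if int(self.s) < 1:
            raise ValueError("s must be a positive integer")
        object.__setattr__(self, "s", int(self.s))

    def symbol(self, freq_mesh: Sequence[np.ndarray]) -> np.ndarray:
        """Spectral symbol of L at integer frequencies (unit domain)."""
        k2 = sum((2.0 * np.pi * k) ** 2 for k in freq_mesh)
        return (1.0 + self.alpha * k2) ** self.s


# ---------------------------------------------------------------------------
# Sobolev operator
# ---------------------------------------------------------------------------


def _apply_symbol(v: VectorField, power: int, spec: RegularizerSpec) -> VectorField:
    _check_finite(v.data, "vector field")
    sym = spec.symbol(v.grid.freq_mesh()) ** power
    axes = tuple(range(1, v.grid.dim + 1))
    vhat = np.fft.fftn(v.data, axes=axes)
    out = np.fft.ifftn(vhat * sym[None], axes=axes).real
    return VectorField(v.grid, out)


def apply_L(v: VectorField, spec: RegularizerSpec) -> VectorField:
    """Apply L = (Id - alpha*Laplacian)^s componentwise via its spectral symbol."""
    return _apply_symbol(v, +1, spec)


def apply_K(v: VectorField, spec: RegularizerSpec) -> VectorField:
    """Apply the inverse K = L^{-1} (symmetric positive definite)."""
    return _apply_symbol(v, -1, spec)


def _bl_symbol(b: BandLimitedField, spec: RegularizerSpec) -> np.ndarray:
    mesh = np.meshgrid(*b.box_freqs(), indexing="ij")
    return spec.symbol(mesh)


def apply_L_bl(b: BandLimitedField, spec: RegularizerSpec) -> BandLimitedField:
    return BandLimitedField(b.bounds, b.coeffs * _bl_symbol(b, spec)[None])


def apply_K_bl(b: BandLimitedField, spec: RegularizerSpec) -> BandLimitedField:
    return BandLimitedField(b.bounds, b.coeffs / _bl_symbol(b, spec)[None])


# ---------------------------------------------------------------------------
# spectral differentiation
# ---------------------------------------------------------------------------


def _spectral_gradient_arr(f: np.ndarray) -> np.ndarray:
    shape = f.shape
    fhat = np.fft.fftn(f)
    mesh = np.meshgrid(*[np.fft.fftfreq(n, d=1.0 / n) for n in shape], indexing="ij")
    out = np.empty((len(shape),) + shape)
    for a, k in enumerate(mesh):
        kk = k.copy()
        if shape[a] % 2 == 0:
            # zero the unpaired Nyquist mode so the derivative stays real/odd
            kk[np.abs(kk) == shape[a] // 2] = 0.0
        out[a] = np.fft.ifftn(2j * np.pi * kk * fhat).real
    return out


def spectral_gradient(f: ScalarField) -> VectorField:
    """Gradient via i*2*pi*k multipliers on the periodic unit domain."""
    return VectorField(f.grid, _spectral_gradient_arr(f.data))


def _spectral_divergence_arr(w: np.ndarray) -> np.ndarray:
    shape = w.shape[1:]
    mesh = np.meshgrid(*[np.fft.fftfreq(n, d=1.0 / n) for n in shape], indexing="ij")
    out = np.zeros(shape)
    for a, k in enumerate(mesh):
        kk = k.copy()
        if shape[a] % 2 == 0:
            kk[np.abs(kk) == shape[a] // 2] = 0.0
        out += np.fft.ifftn(2j * np.pi * kk * np.fft.fftn(w[a])).real
    return out


def spectral_divergence(w: VectorField) -> ScalarField:
    """Divergence; exact negative adjoint of :func:`spectral_gradient`."""
    return ScalarField(w.grid, _spectral_divergence_arr(w.data))


def _fd_gradient_arr(f: np.ndarray) -> np.ndarray:
    """Central differences with periodic wrap, unit-domain spacing."""
    shape = f.shape
    out = np.empty((len(shape),) + shape)
    for a, n in enumerate(shape):
        out[a] = (np.roll(f, -1, axis=a) - np.roll(f, 1, axis=a)) * (0.5 * n)
    return out


def fd_gradient(f: ScalarField) -> VectorField:
    return VectorField(f.grid, _fd_gradient_arr(f.data))


def _fd_divergence_arr(w: np.ndarray) -> np.ndarray:
    shape = w.shape[1:]
    out = np.zeros(shape)
    for a, n in enumerate(shape):
        out += (np.roll(w[a], -1, axis=a) - np.roll(w[a], 1, axis=a)) * (0.5 * n)
    return out


def fd_divergence(w: VectorField) -> ScalarField:
    return ScalarField(w.grid, _fd_divergence_arr(w.data))


# ---------------------------------------------------------------------------
# band-limited algebra
# ---------------------------------------------------------------------------


def _gather_plan(grid_shape: Sequence[int], halfwidths: Sequence[int]):
    """Per-axis index map and weights from a full spectrum to the centered box.

    When the box touches the grid Nyquist plane (h == N/2 for even N) the
    single grid coefficient at index N/2 represents both the +N/2 and -N/2
    series modes; it is split half-half so the round trip through the spatial
    domain is exact.
    """
    idx, wgt = [], []
    for n, h in zip(grid_shape, halfwidths):
        f = np.arange(-h, h + 1)
        idx.append(np.mod(f, n))
        w = np.ones(2 * h + 1)
        if n % 2 == 0 and h == n // 2:
            w[0] = w[-1] = 0.5
        wgt.append(w)
    return idx, wgt


def project_band(w: VectorField, bounds: Sequence[int]) -> BandLimitedField:
    """Projection pi of a spatial field onto the band-limited space."""
    grid = w.grid
    bounds = tuple(int(b) for b in bounds)
    if len(bounds) != grid.dim:
        raise ValueError("bounds must have one entry per axis")
    if any(b > n for b, n in zip(bounds, grid.shape)):
        raise ValueError(f"band bounds {bounds} exceed grid shape {grid.shape}")
    hw = _box_halfwidths(bounds, grid.shape)
    idx, wgt = _gather_plan(grid.shape, hw)
    axes = tuple(range(1, grid.dim + 1))
    spec = np.fft.fftn(w.data, axes=axes, norm="forward")
    box = spec[(slice(None),) + np.ix_(*idx)]
    wall = functools.reduce(np.multiply, np.ix_(*wgt))
    return BandLimitedField(bounds, box * wall[None])


def include_band(b: BandLimitedField, grid: GridSpec) -> VectorField:
    """Natural inclusion iota: lift band coefficients to a real spatial field."""
    if len(b.bounds) != grid.dim:
        raise ValueError("dimension mismatch between band and grid")
    if any(h > n // 2 for h, n in zip(b.halfwidths, grid.shape)):
        raise ValueError(f"band box {b.halfwidths} does not fit grid {grid.shape}")
    idx, _ = _gather_plan(grid.shape, b.halfwidths)
    spec = np.zeros((b.dim,) + grid.shape, dtype=complex)
    flat = np.ravel_multi_index(
        tuple(m.ravel() for m in np.meshgrid(*idx, indexing="ij")), grid.shape
    )
    for c in range(b.dim):
        acc = np.zeros(grid.nvox, dtype=complex)
        np.add.at(acc, flat, b.coeffs[c].ravel())
        spec[c] = acc.reshape(grid.shape)
    axes = tuple(range(1, grid.dim + 1))
    out = np.fft.ifftn(spec, axes=axes, norm="forward").real
    return VectorField(grid, out)


def _next_fast_even(n: int) -> int:
    from scipy.fft import next_fast_len

    m = next_fast_len(n)
    while m % 2:
        m = next_fast_len(m + 1)
    return m


def truncated_convolution(a: BandLimitedField, b: BandLimitedField) -> BandLimitedField:
    """Truncated convolution: pi of the pointwise product of the iota-lifts.

    Computed on a zero-padded grid large enough to hold all product
    frequencies, so no aliasing occurs before the re-truncation.
    """
    if a.halfwidths != b.halfwidths:
        raise ValueError("band bounds of the operands must match")
    hw = a.halfwidths
    pad_shape = tuple(max(_next_fast_even(4 * h + 2), 4) for h in hw)
    grid = GridSpec(pad_shape)
    fa = include_band(a, grid)
    fb = include_band(b, grid)
    prod = VectorField(grid, fa.data * fb.data)
    out = project_band(prod, tuple(2 * h for h in hw))
    return BandLimitedField(a.bounds, out.coeffs)


def bl_contract_jacobian(u: BandLimitedField, v: BandLimitedField) -> BandLimitedField:
    """Band-limited (Du) ★ v: truncated convolution of the spectral Jacobian of
    ``u`` with ``v``, contracted over the derivative axis."""
    if u.halfwidths != v.halfwidths:
        raise ValueError("band bounds of the operands must match")
    mesh = np.meshgrid(*u.box_freqs(), indexing="ij")
    out = np.zeros_like(u.coeffs)
    for j in range(u.dim):
        dj = BandLimitedField(u.bounds, u.coeffs * (2j * np.pi * mesh[j])[None])
        # dj rows: d u_i / d x_j; convolve each with v_j
        vj = BandLimitedField(v.bounds, np.repeat(v.coeffs[j][None], u.dim, axis=0))
        out += truncated_convolution(dj, vj).coeffs
    return BandLimitedField(u.bounds, out)


# ---------------------------------------------------------------------------
# inner products
# ---------------------------------------------------------------------------


def inner(x, y) -> float:
    """Discrete inner product: unit-domain integral for spatial fields,
    plain l2 for band-limited coefficients."""
    if isinstance(x, ScalarField) and isinstance(y, ScalarField):
        return float(np.mean(x.data * y.data))
    if isinstance(x, VectorField) and isinstance(y, VectorField):
        return float(np.sum(np.mean(x.data * y.data, axis=tuple(range(1, x.data.ndim)))))
    if isinstance(x, BandLimitedField) and isinstance(y, BandLimitedField):
        return float(np.sum((x.coeffs * np.conj(y.coeffs)).real))
    raise TypeError(f"unsupported operand types {type(x)}, {type(y)}")
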