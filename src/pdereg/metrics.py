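"""Image similarity metrics: value, initial adjoint, and Gauss-Newton operator.

Each metric produces a :class:`MetricBundle` with three ingredients the
variational machinery consumes:

* ``value``     — E_img including the 1/sigma^2 weight,
* ``lambda1``   — the initial adjoint variable lambda(1) = -dE_img/dm(1),
  i.e. the final condition of the backward adjoint transport,
* ``gn_operator`` — the linear map dm(1) -> dlambda(1) used for Gauss-Newton
  Hessian-vector products; ``None`` for mutual information, whose second-order
  form is not tractable (gradient descent only).

All first-order operators are exact adjoints of the discretization used to
evaluate the metric itself, so ``<lambda1, dm> == -dE_img/deps`` holds to
finite-difference accuracy.  All Gauss-Newton operators are of the form
``-J^T H J`` with ``H`` positive semi-definite, hence ``<dm, -gn(dm)> >= 0``
by construction.

Intensity conventions follow common practice for these metrics: SSD and NCC
expect images scaled to [0, 1]; lNCC, NGF and MI expect [0, 255].  Only MI
depends on the convention structurally (its Parzen bin mapping is a fixed
affine map of the declared intensity range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

from .grid import (
    ScalarField,
    _fd_divergence_arr,
    _fd_gradient_arr,
    _spectral_divergence_arr,
    _spectral_gradient_arr,
)

__all__ = [
    "MetricSpec",
    "MetricBundle",
    "ssd_bundle",
    "ncc_bundle",
    "lncc_bundle",
    "ngf_bundle",
    "parzen_joint",
    "mi_bundle",
    "metric_bundle",
    "METRICS",
]

METRICS = ("ssd", "ncc", "lncc", "ngf", "mi")

# cubic Parzen windows keep their full support inside the histogram when the
# intensity map lands this many bins away from either end
_MI_PAD = 2.0


@dataclass(frozen=True)
class MetricSpec:
    """Configuration of an image similarity metric."""

    kind: str = "ssd"
    sigma2: float = 1.0
    lncc_radius: int = 4
    ngf_eps2: float = 1000.0
    mi_bins: int = 16
    mi_spline_order: int = 3
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self):
        if self.kind not in METRICS:
            raise ValueError(f"unknown metric {self.kind!r}; expected one of {METRICS}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.lncc_radius < 1:
            raise ValueError("lncc_radius must be >= 1")
        if self.ngf_eps2 <= 0:
            raise ValueError("ngf_eps2 must be > 0")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.mi_spline_order != 3:
            raise ValueError("only the cubic Parzen window is implemented")

    @property
    def supports_gauss_newton(self) -> bool:
        return self.kind != "mi"


@dataclass
class MetricBundle:
    """E_img, the initial adjoint, and the Gauss-Newton incremental map."""

    value: float
    lambda1: ScalarField
    gn_operator: Optional[Callable[[ScalarField], ScalarField]] = None
    intermediates: dict = field(default_factory=dict)


def _check_grids(m1: ScalarField, i1: ScalarField) -> None:
    if m1.grid.shape != i1.grid.shape:
        raise ValueError(
            f"image grids differ: {m1.grid.shape} vs {i1.grid.shape}"
        )


# ---------------------------------------------------------------------------
# SSD
# ---------------------------------------------------------------------------


def ssd_bundle(m1: ScalarField, i1: ScalarField, spec: MetricSpec) -> MetricBundle:
    """Sum of squared differences: E = (1/sigma^2) * ||m(1) - I1||^2."""
    _check_grids(m1, i1)
    s2 = spec.sigma2
    resid = m1.data - i1.data
    value = float(np.mean(resid**2)) / s2
    lam1 = ScalarField(m1.grid, -(2.0 / s2) * resid)

    def gn(dm: ScalarField) -> ScalarField:
        return ScalarField(dm.grid, -(2.0 / s2) * dm.data)

    return MetricBundle(value, lam1, gn, {"residual": resid})


# ---------------------------------------------------------------------------
# NCC (global squared normalized cross-correlation)
# ---------------------------------------------------------------------------


def ncc_bundle(m1: ScalarField, i1: ScalarField, spec: MetricSpec) -> MetricBundle:
    """Global NCC: E = (1/sigma^2) (1 - A^2/(B C)) with A = <m_c, I_c>,
    B = ||m_c||^2, C = ||I_c||^2 on mean-removed images.

    The Gauss-Newton map is the residual-form J^T J of the orthogonality
    residual r = m_c/sqrt(B) - rho * I_c/sqrt(C); it is PSD and coincides with
    the differential of lambda(1) at zero residual.
    """
    _check_grids(m1, i1)
    s2 = spec.sigma2
    mc = m1.data - m1.data.mean()
    ic = i1.data - i1.data.mean()
    A = float(np.mean(mc * ic))
    B = float(np.mean(mc * mc))
    C = float(np.mean(ic * ic))
    floor = 1e-10 * max(np.abs(m1.data).max(), np.abs(i1.data).max(), 1.0) ** 2
    if B < floor or C < floor:
        raise ValueError("NCC undefined for (near-)constant images")
    kappa = A / B
    value = (1.0 - A * A / (B * C)) / s2
    lam1 = ScalarField(m1.grid, (2.0 / (s2 * C)) * (kappa * ic - kappa**2 * mc))

    rho = A / np.sqrt(B * C)
    q = (ic - kappa * mc) / np.sqrt(B * C)

    def jac(dm: np.ndarray) -> np.ndarray:
        dmc = dm - dm.mean()
        b = float(np.mean(mc * dmc))
        drho = float(np.mean(q * dm))
        return dmc / np.sqrt(B) - (b / B) * mc / np.sqrt(B) - drho * ic / np.sqrt(C)

    def jac_t(w: np.ndarray) -> np.ndarray:
        wc = w - w.mean()
        return (
            wc / np.sqrt(B)
            - (float(np.mean(mc * w)) / B**1.5) * mc
            - (float(np.mean(ic * w)) / np.sqrt(C)) * q
        )

    def gn(dm: ScalarField) -> ScalarField:
        return ScalarField(dm.grid, -(2.0 / s2) * jac_t(jac(dm.data)))

    return MetricBundle(value, lam1, gn, {"A": A, "B": B, "C": C, "rho": rho})


# ---------------------------------------------------------------------------
# lNCC (windowed local version)
# ---------------------------------------------------------------------------


def _boxmean(a: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.uniform_filter(a, size=2 * radius + 1, mode="wrap")


def lncc_bundle(m1: ScalarField, i1: ScalarField, spec: MetricSpec) -> MetricBundle:
    """Local NCC over box neighborhoods of half-width ``lncc_radius``.

    A, B, C become fields of windowed (co)variances; the adjoint re-applies
    the (self-adjoint) box window wherever the chain rule passes through it.
    """
    _check_grids(m1, i1)
    nu = spec.lncc_radius
    if any(2 * nu + 1 > n for n in m1.grid.shape):
        raise ValueError("lNCC window larger than the image")
    s2 = spec.sigma2
    m, I = m1.data, i1.data
    P = lambda a: _boxmean(a, nu)
    mu_m, mu_i = P(m), P(I)
    A = P(m * I) - mu_m * mu_i
    B = P(m * m) - mu_m**2
    C = P(I * I) - mu_i**2
    Bf = np.maximum(B, 1e-10 * max(B.max(), 1e-30))
    Cf = np.maximum(C, 1e-10 * max(C.max(), 1e-30))
    r = A * A / (Bf * Cf)
    value = float(np.mean(1.0 - r)) / s2

    g_a = 2.0 * A / (Bf * Cf)
    g_b = -(A * A) / (Bf * Bf * Cf)
    lam1 = ScalarField(
        m1.grid,
        (I * P(g_a) - P(mu_i * g_a) + 2.0 * (m * P(g_b) - P(mu_m * g_b))) / s2,
    )

    sqBC = np.sqrt(Bf * Cf)
    kap = A / Bf
    rho = A / sqBC
    sqB, sqC = np.sqrt(Bf), np.sqrt(Cf)

    def drho(dm: np.ndarray) -> np.ndarray:
        dA = P(I * dm) - mu_i * P(dm)
        dB = 2.0 * (P(m * dm) - mu_m * P(dm))
        return (dA - 0.5 * kap * dB) / sqBC

    def drho_t(w: np.ndarray) -> np.ndarray:
        wh = w / sqBC
        return I * P(wh) - P(mu_i * wh) - m * P(kap * wh) + P(mu_m * kap * wh)

    # Residual form: 1 - rho(x)^2 = mean over the window at x of
    # r(x, y) = (m(y) - mu_m(x))/sqrt(B(x)) - rho(x) (I(y) - mu_i(x))/sqrt(C(x));
    # the Gauss-Newton operator is the exact J^T J of that residual, assembled
    # with box filters only.  dr decomposes per window as
    # dr = dm(y) s(x) + m(y) c2(x) + I(y) c3(x) + c4(x).
    s = 1.0 / sqB

    def _coeffs(dm: np.ndarray):
        dB = 2.0 * (P(m * dm) - mu_m * P(dm))
        dr_ = drho(dm)
        c2 = -0.5 * dB / Bf**1.5
        c3 = -dr_ / sqC
        c4 = -P(dm) * s - mu_m * c2 - mu_i * c3
        return c2, c3, c4

    def gn(dm: ScalarField) -> ScalarField:
        d = dm.data
        c2, c3, c4 = _coeffs(d)
        # direct path: mean over offsets of the shifted residual times s
        direct = d * P(s * s) + m * P(s * c2) + I * P(s * c3) + P(s * c4)
        # window-correlations of the residual against m, I and 1
        g2 = P(d * m) * s + P(m * m) * c2 + P(m * I) * c3 + P(m) * c4
        g3 = P(d * I) * s + P(m * I) * c2 + P(I * I) * c3 + P(I) * c4
        g4 = P(d) * s + P(m) * c2 + P(I) * c3 + c4
        # adjoints of c2, c3, c4 as linear maps of dm
        w2 = g2 - mu_m * g4
        adj_c2 = -(m * P(w2 / Bf**1.5) - P(mu_m * w2 / Bf**1.5))
        w3 = (g3 - mu_i * g4) / sqC
        adj_c3 = -drho_t(w3)
        adj_c4 = -P(g4 * s)
        out = direct + adj_c2 + adj_c3 + adj_c4
        return ScalarField(dm.grid, -(2.0 / s2) * out)

    return MetricBundle(value, lam1, gn, {"A": A, "B": B, "C": C})


# ---------------------------------------------------------------------------
# NGF (normalized gradient fields)
# ---------------------------------------------------------------------------


def _grad_vox(f: np.ndarray, stencil: str) -> np.ndarray:
    """Gradient in voxel units (spacing 1), spectral or central-difference."""
    n = np.asarray(f.shape, dtype=float).reshape((-1,) + (1,) * f.ndim)
    if stencil == "spectral":
        return _spectral_gradient_arr(f) / n
    out = np.empty((f.ndim,) + f.shape)
    for a in range(f.ndim):
        out[a] = 0.5 * (np.roll(f, -1, axis=a) - np.roll(f, 1, axis=a))
    return out


def _div_vox(w: np.ndarray, stencil: str) -> np.ndarray:
    n = np.asarray(w.shape[1:], dtype=float).reshape((-1,) + (1,) * (w.ndim - 1))
    if stencil == "spectral":
        return _spectral_divergence_arr(w / n)
    out = np.zeros(w.shape[1:])
    for a in range(w.ndim - 1):
        out += 0.5 * (np.roll(w[a], -1, axis=a) - np.roll(w[a], 1, axis=a))
    return out


def ngf_bundle(m1: ScalarField, i1: ScalarField, spec: MetricSpec) -> MetricBundle:
    """Normalized gradient fields: E = (1/sigma^2) * mean(1 - r^2) with
    r = (<grad m, grad I> + eps^2) / (||grad m||_eps ||grad I||_eps).

    Image gradients use voxel spacing so the default eps^2 = 1000 has its
    conventional scale for [0, 255] images.  The first-order path uses the
    spectral operators (consistent with the value); the Gauss-Newton path uses
    matched central-difference gradient/divergence stencils.
    """
    _check_grids(m1, i1)
    s2 = spec.sigma2
    eps2 = spec.ngf_eps2

    gm = _grad_vox(m1.data, "spectral")
    gi = _grad_vox(i1.data, "spectral")
    A = np.sum(gm * gi, axis=0) + eps2
    B = np.sqrt(np.sum(gm * gm, axis=0) + eps2)
    C = np.sqrt(np.sum(gi * gi, axis=0) + eps2)
    r = A / (B * C)
    value = float(np.mean(1.0 - r * r)) / s2

    w = (A / (B * C) ** 2) * gi - (A * A / (B**4 * C**2)) * gm
    # adjoint of the spectral voxel-unit gradient is minus its divergence
    n = np.asarray(m1.grid.shape, dtype=float).reshape((-1,) + (1,) * m1.grid.dim)
    div_w = _spectral_divergence_arr(w / n)
    lam1 = ScalarField(m1.grid, -(2.0 / s2) * div_w)

    gm_fd = _grad_vox(m1.data, "fd")
    gi_fd = _grad_vox(i1.data, "fd")
    A_fd = np.sum(gm_fd * gi_fd, axis=0) + eps2
    B_fd = np.sqrt(np.sum(gm_fd * gm_fd, axis=0) + eps2)
    C_fd = np.sqrt(np.sum(gi_fd * gi_fd, axis=0) + eps2)
    p = (gi_fd - (A_fd / B_fd**2) * gm_fd) / (B_fd * C_fd)

    def gn(dm: ScalarField) -> ScalarField:
        dr = np.sum(p * _grad_vox(dm.data, "fd"), axis=0)
        return ScalarField(dm.grid, -(2.0 / s2) * (-_div_vox(p * dr, "fd")))

    return MetricBundle(value, lam1, gn, {"A": A, "B": B, "C": C, "r": r})


# ---------------------------------------------------------------------------
# MI (mutual information with cubic Parzen windows)
# ---------------------------------------------------------------------------


def _parzen_coords(a: np.ndarray, spec: MetricSpec) -> tuple[np.ndarray, float]:
    """Map intensities into bin coordinates so the cubic window's support
    stays inside [0, bins-1]; returns coordinates and the affine slope."""
    lo, hi = spec.intensity_range
    width = hi - lo
    if width <= 0:
        raise ValueError("empty intensity range")
    slope = (spec.mi_bins - 1 - 2 * _MI_PAD) / width
    t = _MI_PAD + (np.clip(a, lo, hi) - lo) * slope
    return t, slope


def _spline_w(t: np.ndarray) -> list[np.ndarray]:
    t2, t3 = t * t, t * t * t
    return [
        (1.0 - 3.0 * t + 3.0 * t2 - t3) / 6.0,
        (4.0 - 6.0 * t2 + 3.0 * t3) / 6.0,
        (1.0 + 3.0 * t + 3.0 * t2 - 3.0 * t3) / 6.0,
        t3 / 6.0,
    ]


def _spline_dw(t: np.ndarray) -> list[np.ndarray]:
    """Derivatives of the four window weights w.r.t. the bin coordinate."""
    t2 = t * t
    return [
        -(1.0 - 2.0 * t + t2) / 2.0,
        (-4.0 * t + 3.0 * t2) / 2.0,
        (1.0 + 2.0 * t - 3.0 * t2) / 2.0,
        t2 / 2.0,
    ]


def parzen_joint(m1: ScalarField, i1: ScalarField, spec: MetricSpec):
    """Parzen-window joint and marginal intensity distributions.

    p(r, s) = (1/N) sum_x xi(r - t_m(x)) xi(s - t_I(x)) with the cubic
    B-spline window xi; the joint sums to one exactly and the marginals are
    its row/column sums.
    """
    _check_grids(m1, i1)
    nb = spec.mi_bins
    tm, _ = _parzen_coords(m1.data, spec)
    ti, _ = _parzen_coords(i1.data, spec)
    if np.ptp(tm) < 1e-9 or np.ptp(ti) < 1e-9:
        raise ValueError("degenerate intensity distribution: constant image")
    bm, bi = np.floor(tm).astype(int), np.floor(ti).astype(int)
    wm, wi = _spline_w(tm - bm), _spline_w(ti - bi)
    p = np.zeros((nb, nb))
    n = tm.size
    for om in range(4):
        rm = (bm - 1 + om).ravel()
        for oi in range(4):
            ri = (bi - 1 + oi).ravel()
            np.add.at(p, (rm, ri), (wm[om] * wi[oi]).ravel() / n)
    p_m = p.sum(axis=1)
    p_i = p.sum(axis=0)
    if np.count_nonzero(p_m > 1e-12) < 2 or np.count_nonzero(p_i > 1e-12) < 2:
        raise ValueError("degenerate intensity distribution: fewer than 2 occupied bins")
    return p, p_m, p_i


def _entropy(p: np.ndarray) -> float:
    q = p[p > 0]
    return float(-np.sum(q * np.log(q)))


def mi_bundle(m1: ScalarField, i1: ScalarField, spec: MetricSpec) -> MetricBundle:
    """Mutual information: E = -(1/sigma^2) (H(m) + H(I) - H(m, I)).

    The initial adjoint follows from the analytic Parzen density: the window
    derivative paired with 1 + log(p_joint / p_marginal) gathered at each
    voxel's occupied cells.  No Gauss-Newton operator exists for MI.
    """
    _check_grids(m1, i1)
    s2 = spec.sigma2
    p, p_m, p_i = parzen_joint(m1, i1, spec)
    value = -(_entropy(p_m) + _entropy(p_i) - _entropy(p)) / s2

    with np.errstate(divide="ignore", invalid="ignore"):
        L = 1.0 + np.log(np.where(p > 0, p, 1.0)) - np.log(np.where(p_m > 0, p_m, 1.0))[:, None]
    L[p <= 0] = 0.0

    tm, slope = _parzen_coords(m1.data, spec)
    ti, _ = _parzen_coords(i1.data, spec)
    bm, bi = np.floor(tm).astype(int), np.floor(ti).astype(int)
    dwm = _spline_dw(tm - bm)
    wi = _spline_w(ti - bi)
    acc = np.zeros(m1.grid.shape)
    for om in range(4):
        rm = bm - 1 + om
        for oi in range(4):
            ri = bi - 1 + oi
            acc += dwm[om] * wi[oi] * L[rm, ri]
    lam1 = ScalarField(m1.grid, (slope / s2) * acc)
    return MetricBundle(value, lam1, None, {"p": p, "p_m": p_m, "p_i": p_i})


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_DISPATCH = {
    "ssd": ssd_bundle,
    "ncc": ncc_bundle,
    "lncc": lncc_bundle,
    "ngf": ngf_bundle,
    "mi": mi_bundle,
}


def metric_bundle(m1: ScalarField, i1: ScalarField, spec: MetricSpec) -> MetricBundle:
    """Evaluate the metric named by ``spec.kind``."""
    return _DISPATCH[spec.kind](m1, i1, spec)
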