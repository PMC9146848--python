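"""Gradient-descent and Gauss-Newton-Krylov drivers.

Both optimizers precondition with K = L^{-1}: gradient descent steps along
-K grad E (a Sobolev gradient step), Gauss-Newton-Krylov solves
H dv = -grad E with preconditioned conjugate gradient (at most ``pcg_iters``
iterations, forcing tolerance min(0.5, sqrt(|g_n|/|g_0|))) and falls back to
the Sobolev direction if PCG returns a non-descent direction.  Step sizes are
chosen by backtracking with the Armijo sufficient-decrease condition, so the
energy trace over accepted steps is non-increasing by construction.

``multiresolution_run`` embeds either driver in a coarse-to-fine pyramid
(default three levels, subsampling factors 4/2/1 with Gaussian anti-aliasing);
velocities move between levels by exact Fourier embedding, which for the
band-limited parameterization is just a re-embedding of the coefficient box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

from .grid import (
    BandLimitedField,
    GridSpec,
    ScalarField,
    VectorField,
    include_band,
    inner,
    project_band,
)
from .transport import solve_deformation, solve_jacobian
from .variants import ObjectiveState, ProblemSpec, RegistrationProblem, Velocity

__all__ = [
    "OptimizerConfig",
    "RegistrationResult",
    "armijo_backtrack",
    "pcg_solve",
    "gd_step",
    "gnk_step",
    "stopping_check",
    "optimize_velocity",
    "multiresolution_run",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimizerConfig:
    """Optimization parameters; defaults follow the standard single-resolution
    setup (50 gradient-descent or 10 Gauss-Newton-Krylov outer iterations,
    5 PCG iterations)."""

    method: str = "gnk"
    max_outer: Optional[int] = None
    pcg_iters: int = 5
    armijo_c: float = 1e-4
    step_init: float = 1.0
    step_shrink: float = 0.5
    max_backtracks: int = 10
    tol_grad: float = 1e-2
    tol_energy: float = 1e-4
    levels: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("gd", "gnk"):
            raise ValueError("method must be 'gd' or 'gnk'")
        if self.pcg_iters < 1:
            raise ValueError("pcg_iters must be >= 1")
        if not 0.0 < self.armijo_c < 1.0:
            raise ValueError("armijo_c must be in (0, 1)")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")

    @property
    def outer_iters(self) -> int:
        if self.max_outer is not None:
            return self.max_outer
        return 50 if self.method == "gd" else 10


@dataclass
class RegistrationResult:
    """Final velocity plus diagnostics of one (multi-level) optimization."""

    v: Velocity
    v_spatial: VectorField
    phi_disp: VectorField
    psi_disp: VectorField
    jac_min: float
    jac_max: float
    warped: ScalarField
    energy_trace: list[float]
    e_img_trace: list[float]
    grad_rel_trace: list[float]
    stop_reason: str
    level_traces: list[dict] = field(default_factory=list)


def _norm_inf(v: Velocity) -> float:
    if isinstance(v, BandLimitedField):
        return float(np.abs(v.coeffs).max())
    return float(np.abs(v.data).max())


# ---------------------------------------------------------------------------
# line search
# ---------------------------------------------------------------------------


def armijo_backtrack(
    prob: RegistrationProblem,
    state: ObjectiveState,
    grad: Velocity,
    direction: Velocity,
    config: OptimizerConfig,
    step_init: Optional[float] = None,
):
    """Backtracking line search under the Armijo sufficient-decrease condition.

    Returns (step, new_state) or (0.0, None) when no admissible step exists
    within ``max_backtracks`` halvings.  Raises if ``direction`` is not a
    descent direction.
    """
    slope = inner(grad, direction)
    if slope >= 0.0:
        raise ValueError("not a descent direction (<g, d> >= 0)")
    step = config.step_init if step_init is None else step_init
    for _ in range(config.max_backtracks):
        trial = prob.objective(state.v + step * direction)
        if trial.energy <= state.energy + config.armijo_c * step * slope:
            return step, trial
        step *= config.step_shrink
    return 0.0, None


# ---------------------------------------------------------------------------
# PCG
# ---------------------------------------------------------------------------


def pcg_solve(
    hvp: Callable[[Velocity], Velocity],
    rhs: Velocity,
    precond: Callable[[Velocity], Velocity],
    max_iters: int = 5,
    tol: float = 0.5,
):
    """Preconditioned conjugate gradient for a symmetric PSD operator.

    Stops after ``max_iters`` iterations or when the residual norm drops
    below ``tol`` times its initial value; detecting non-positive curvature
    aborts and returns the current iterate (flagged in the info dict).
    """
    x = 0.0 * rhs
    r = rhs
    z = precond(r)
    p = z
    rz = inner(r, z)
    r0 = np.sqrt(max(inner(r, r), 0.0))
    info = {"iters": 0, "negative_curvature": False, "residuals": [1.0]}
    if r0 == 0.0:
        return x, info
    for it in range(max_iters):
        hp = hvp(p)
        php = inner(p, hp)
        if php <= 0.0:
            info["negative_curvature"] = True
            if it == 0:
                x = p  # fall back to the preconditioned residual direction
            break
        alpha = rz / php
        x = x + alpha * p
        r = r - alpha * hp
        info["iters"] = it + 1
        rnorm = np.sqrt(max(inner(r, r), 0.0))
        info["residuals"].append(rnorm / r0)
        if rnorm <= tol * r0:
            break
        z = precond(r)
        rz_new = inner(r, z)
        beta = rz_new / rz
        rz = rz_new
        p = z + beta * p
    return x, info


# ---------------------------------------------------------------------------
# steps
# ---------------------------------------------------------------------------


def gd_step(
    prob: RegistrationProblem,
    state: ObjectiveState,
    config: OptimizerConfig,
    step_init: Optional[float] = None,
):
    """One Sobolev gradient-descent step v <- v - eps K grad(E)."""
    grad = state.gradient if state.gradient is not None else prob.gradient(state)
    if _norm_inf(grad) == 0.0:
        return 0.0, state, grad
    direction = -1.0 * prob.apply_K_space(grad)
    step, new_state = armijo_backtrack(prob, state, grad, direction, config, step_init)
    return step, new_state, grad


def gnk_step(
    prob: RegistrationProblem,
    state: ObjectiveState,
    config: OptimizerConfig,
    grad0_norm: Optional[float] = None,
    step_init: Optional[float] = None,
):
    """One Gauss-Newton-Krylov step: PCG on H dv = -g, then line search."""
    if not prob.spec.metric.supports_gauss_newton:
        raise ValueError("Gauss-Newton-Krylov is not supported with mutual information")
    grad = state.gradient if state.gradient is not None else prob.gradient(state)
    gnorm = np.sqrt(max(inner(grad, grad), 0.0))
    if gnorm == 0.0:
        return 0.0, state, grad, {"iters": 0}
    tol = 0.5
    if grad0_norm is not None and grad0_norm > 0:
        tol = min(0.5, np.sqrt(gnorm / grad0_norm))
    dv, info = pcg_solve(
        lambda w: prob.hvp(state, w),
        -1.0 * grad,
        prob.apply_K_space,
        max_iters=config.pcg_iters,
        tol=tol,
    )
    if inner(grad, dv) >= 0.0:
        dv = -1.0 * prob.apply_K_space(grad)
        info["fallback"] = True
    step, new_state = armijo_backtrack(prob, state, grad, dv, config, step_init)
    return step, new_state, grad, info


def stopping_check(
    grad_rel: float, energy_trace: list[float], config: OptimizerConfig
) -> Optional[str]:
    """Stopping rules: relative gradient, relative energy stagnation over two
    iterations, and iteration budget (checked by the caller)."""
    if grad_rel <= config.tol_grad:
        return "gradient"
    if len(energy_trace) >= 3:
        e2, e1, e0 = energy_trace[-3], energy_trace[-2], energy_trace[-1]
        scale = max(abs(energy_trace[0]), 1e-30)
        if abs(e1 - e0) / scale <= config.tol_energy and abs(e2 - e1) / scale <= config.tol_energy:
            return "energy"
    return None


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def optimize_velocity(
    prob: RegistrationProblem,
    config: OptimizerConfig,
    v0: Optional[Velocity] = None,
):
    """Run the configured optimizer from ``v0`` (zero velocity by default).

    Returns (state, trace) where trace collects per-iteration energies,
    image terms, relative gradient norms and the stop reason.
    """
    state = prob.objective(v0 if v0 is not None else prob.zero_velocity())
    grad = prob.gradient(state)
    g0_inf = _norm_inf(grad)
    g0_l2 = np.sqrt(max(inner(grad, grad), 0.0))
    trace = {
        "energy": [state.energy],
        "e_img": [state.e_img],
        "e_reg": [state.e_reg],
        "grad_rel": [1.0],
        "steps": [],
        "stop_reason": "max_outer",
    }
    if g0_inf == 0.0:
        trace["stop_reason"] = "gradient"
        return state, trace
    step_next = config.step_init
    for it in range(config.outer_iters):
        if config.method == "gd":
            step, new_state, grad = gd_step(prob, state, config, step_init=step_next)
        else:
            step, new_state, grad, _ = gnk_step(
                prob, state, config, grad0_norm=g0_l2, step_init=step_next
            )
        if step == 0.0 or new_state is None:
            trace["stop_reason"] = "stagnation"
            break
        state = new_state
        grad = prob.gradient(state)
        grel = _norm_inf(grad) / g0_inf
        trace["energy"].append(state.energy)
        trace["e_img"].append(state.e_img)
        trace["e_reg"].append(state.e_reg)
        trace["grad_rel"].append(grel)
        trace["steps"].append(step)
        log.info(
            "it %2d  E=%.6e  e_img=%.6e  e_reg=%.3e  step=%.3g  |g|rel=%.3e",
            it + 1, state.energy, state.e_img, state.e_reg, step, grel,
        )
        reason = stopping_check(grel, trace["energy"], config)
        if reason is not None:
            trace["stop_reason"] = reason
            break
        # allow the accepted step to grow again next iteration
        step_next = min(config.step_init, step / config.step_shrink)
    return state, trace


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img.copy()
    smoothed = ndimage.gaussian_filter(img, sigma=0.5 * factor, mode="wrap")
    sl = tuple(slice(None, None, factor) for _ in img.shape)
    return smoothed[sl]


def _upsample_velocity(v: Velocity, coarse: GridSpec, fine: GridSpec, spec: ProblemSpec) -> Velocity:
    """Move a velocity to the next finer grid by exact Fourier embedding."""
    if isinstance(v, BandLimitedField):
        bounds = spec.bounds_for(fine)
        out = BandLimitedField.zeros(bounds, fine.shape)
        hw_new = out.halfwidths
        hw_old = v.halfwidths
        sl = tuple(
            slice(hn - ho, hn + ho + 1) for hn, ho in zip(hw_new, hw_old)
        )
        coeffs = out.coeffs.copy()
        coeffs[(slice(None),) + sl] = v.coeffs
        return BandLimitedField(bounds, coeffs)
    band = project_band(v, coarse.shape)
    return include_band(band, fine)


def multiresolution_run(
    i0: ScalarField,
    i1: ScalarField,
    spec: ProblemSpec,
    config: OptimizerConfig,
) -> RegistrationResult:
    """Coarse-to-fine registration of ``i0`` onto ``i1``.

    With ``levels = L`` the pyramid uses subsampling factors 2^(L-1) ... 1;
    each level runs the full iteration budget; the velocity is upsampled by
    Fourier embedding between levels.  The returned result carries the final
    deformation, its inverse, Jacobian extrema and traces per level.
    """
    grid = i0.grid
    factors = [2 ** (config.levels - 1 - l) for l in range(config.levels)]
    if any(n // factors[0] < 4 for n in grid.shape):
        raise ValueError(
            f"image of shape {grid.shape} too small for {config.levels} levels"
        )
    v = None
    prev_grid = None
    level_traces = []
    prob = None
    state = None
    for factor in factors:
        shape = tuple(n // factor for n in grid.shape)
        lg = GridSpec(shape)
        li0 = ScalarField(lg, _downsample(i0.data, factor))
        li1 = ScalarField(lg, _downsample(i1.data, factor))
        prob = RegistrationProblem(li0, li1, spec)
        if v is None:
            v = prob.zero_velocity()
        else:
            v = _upsample_velocity(v, prev_grid, lg, spec)
        state, trace = optimize_velocity(prob, config, v)
        v = state.v
        prev_grid = lg
        level_traces.append({"factor": factor, **trace})
        log.info("level x%d done: E=%.6e (%s)", factor, state.energy, trace["stop_reason"])
    v_sp = state.v_spatial
    tg = prob.timegrid
    psi = solve_deformation(v_sp, tg, "inverse", flow=state.flow)
    jac = solve_jacobian(v_sp, tg, flow=state.flow)
    last = level_traces[-1]
    return RegistrationResult(
        v=v,
        v_spatial=v_sp,
        phi_disp=state.phi_disp[-1],
        psi_disp=psi[0],
        jac_min=float(jac[0].data.min()),
        jac_max=float(jac[0].data.max()),
        warped=ScalarField(prob.grid, state.m[-1]),
        energy_trace=last["energy"],
        e_img_trace=last["e_img"],
        grad_rel_trace=last["grad_rel"],
        stop_reason=last["stop_reason"],
        level_traces=level_traces,
    )
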