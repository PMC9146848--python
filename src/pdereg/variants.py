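"""Objective, gradient, and Gauss-Newton Hessian-vector products.

Two theoretically equivalent variational formulations are implemented; they
share the same discrete objective (the warped image is always the composition
m(1) = I0 o phi(1) with phi from the deformation state equation) but assemble
first- and second-order information along different routes:

* **Variant I** transports the adjoint variable with the change-of-variables
  identity lambda(t) = J(t) * lambda(1) o psi(t) (inverse map and Jacobian
  from their own backward PDEs) and accumulates the gradient
  Lv + integral of lambda(t) grad m(t) dt with Clenshaw-Curtis quadrature on
  the CGL nodes.
* **Variant II** transports the vector adjoint rho of the deformation state
  equation: rho(1) = lambda(1) * (grad I0) o phi(1), backward continuity
  transport, gradient Lv + integral of Dphi(t)^T rho(t) dt.

Gauss-Newton Hessian-vector products are built as the exact transpose of the
linearized forward solve (incremental state for Variant I, incremental
deformation for Variant II) around the metric's PSD operator, so the induced
quadratic form is positive semi-definite and the assembled Hessian is
symmetric to machine precision.

In the band-limited parameterization the transport runs on the lifted
velocity iota(v~) and gradients/Hessian products are projected back with pi;
with a full band this reduces exactly to the spatial formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .grid import (
    BandLimitedField,
    GridSpec,
    ScalarField,
    VectorField,
    apply_K,
    apply_K_bl,
    apply_L,
    apply_L_bl,
    include_band,
    inner,
    project_band,
    RegularizerSpec,
    _spectral_gradient_arr,
)
from .metrics import MetricBundle, MetricSpec, metric_bundle
from .transport import (
    Flow,
    TimeGrid,
    cgl_nodes,
    clenshaw_curtis_weights,
    solve_deformation,
    solve_jacobian,
    _gather,
    _prefilter,
)

__all__ = [
    "ProblemSpec",
    "ObjectiveState",
    "RegistrationProblem",
    "evaluate_objective",
    "gradient_variant1",
    "gradient_variant2",
    "hvp_variant1",
    "hvp_variant2",
]

Velocity = Union[VectorField, BandLimitedField]


@dataclass(frozen=True)
class ProblemSpec:
    """Which formulation to assemble: variant, parameterization, metric,
    regularizer, band bounds and temporal discretization."""

    variant: int = 2
    parameterization: str = "spatial"
    metric: MetricSpec = field(default_factory=MetricSpec)
    regularizer: RegularizerSpec = field(default_factory=RegularizerSpec)
    band_bounds: Optional[tuple[int, ...]] = None
    n_timesteps: int = 5
    nsub: int = 2

    def __post_init__(self):
        if self.variant not in (1, 2):
            raise ValueError("variant must be 1 or 2")
        if self.parameterization not in ("spatial", "bl"):
            raise ValueError("parameterization must be 'spatial' or 'bl'")
        if self.n_timesteps < 1:
            raise ValueError("n_timesteps must be >= 1")

    def bounds_for(self, grid: GridSpec) -> tuple[int, ...]:
        b = self.band_bounds if self.band_bounds is not None else (32,) * grid.dim
        return tuple(min(int(bb), n) for bb, n in zip(b, grid.shape))


@dataclass
class ObjectiveState:
    """Everything needed to evaluate derivatives at one velocity iterate."""

    v: Velocity
    v_spatial: VectorField
    energy: float
    e_reg: float
    e_img: float
    bundle: MetricBundle
    flow: Flow
    phi_disp: list[VectorField]
    m: list[np.ndarray]
    gradient: Optional[Velocity] = None


class RegistrationProblem:
    """A source/target image pair plus a :class:`ProblemSpec`.

    Exposes objective/gradient/Hessian-vector products in the velocity space
    chosen by the parameterization, and the metric operators L and K in that
    same space.  The Gauss-Newton map is refused for mutual information.
    """

    def __init__(self, i0: ScalarField, i1: ScalarField, spec: ProblemSpec):
        if i0.grid.shape != i1.grid.shape:
            raise ValueError("source and target images must share a grid")
        self.i0 = i0
        self.i1 = i1
        self.spec = spec
        self.grid = i0.grid
        self.timegrid = cgl_nodes(spec.n_timesteps)
        self._cc = clenshaw_curtis_weights(spec.n_timesteps)
        self._i0_coeffs = _prefilter(i0.data)
        self._grad_i0 = _spectral_gradient_arr(i0.data)
        self._grad_i0_coeffs = np.stack([_prefilter(c) for c in self._grad_i0])
        self._scale = np.asarray(self.grid.shape, dtype=float).reshape(
            (-1,) + (1,) * self.grid.dim
        )

    # -- velocity space helpers --------------------------------------------

    @property
    def is_bl(self) -> bool:
        return self.spec.parameterization == "bl"

    def zero_velocity(self) -> Velocity:
        if self.is_bl:
            return BandLimitedField.zeros(self.spec.bounds_for(self.grid), self.grid.shape)
        return VectorField.zeros(self.grid)

    def lift(self, v: Velocity) -> VectorField:
        return include_band(v, self.grid) if self.is_bl else v

    def restrict(self, w: VectorField) -> Velocity:
        if self.is_bl:
            return project_band(w, self.spec.bounds_for(self.grid))
        return w

    def apply_L_space(self, v: Velocity) -> Velocity:
        if self.is_bl:
            return apply_L_bl(v, self.spec.regularizer)
        return apply_L(v, self.spec.regularizer)

    def apply_K_space(self, v: Velocity) -> Velocity:
        if self.is_bl:
            return apply_K_bl(v, self.spec.regularizer)
        return apply_K(v, self.spec.regularizer)

    # -- objective ----------------------------------------------------------

    def objective(self, v: Velocity) -> ObjectiveState:
        v_sp = self.lift(v)
        flow = Flow(v_sp, self.timegrid, self.spec.nsub)
        phi_disp = solve_deformation(v_sp, self.timegrid, "forward", flow=flow)
        base = flow._base
        m = [
            _gather(self._i0_coeffs, base + u.data * self._scale)
            for u in phi_disp
        ]
        bundle = metric_bundle(ScalarField(self.grid, m[-1]), self.i1, self.spec.metric)
        e_reg = inner(self.apply_L_space(v), v)
        energy = 0.5 * e_reg + bundle.value
        return ObjectiveState(
            v=v,
            v_spatial=v_sp,
            energy=energy,
            e_reg=e_reg,
            e_img=bundle.value,
            bundle=bundle,
            flow=flow,
            phi_disp=phi_disp,
            m=m,
        )

    # -- shared pieces ------------------------------------------------------

    def _grad_m(self, state: ObjectiveState) -> list[np.ndarray]:
        return [_spectral_gradient_arr(mn) for mn in state.m]

    def _g_vec(self, state: ObjectiveState) -> np.ndarray:
        """(grad I0) o phi(1)."""
        pts = state.flow._base + state.phi_disp[-1].data * self._scale
        return np.stack([_gather(c, pts) for c in self._grad_i0_coeffs])

    def _dphi(self, state: ObjectiveState) -> list[np.ndarray]:
        """Per-node Jacobians D(phi) = Id + D(u), shape (d, d, *grid)."""
        d = self.grid.dim
        out = []
        for u in state.phi_disp:
            J = np.stack([_spectral_gradient_arr(u.data[i]) for i in range(d)])
            for i in range(d):
                J[i, i] += 1.0
            out.append(J)
        return out

    @staticmethod
    def _mat_vec(J: np.ndarray, w: np.ndarray) -> np.ndarray:
        return np.einsum("ij...,j...->i...", J, w)

    @staticmethod
    def _mat_t_vec(J: np.ndarray, w: np.ndarray) -> np.ndarray:
        return np.einsum("ij...,i...->j...", J, w)

    # -- gradients ----------------------------------------------------------

    def gradient(self, state: ObjectiveState) -> Velocity:
        if self.spec.variant == 1:
            img = self._image_term_variant1(state)
        else:
            img = self._image_term_variant2(state)
        img_f = VectorField(self.grid, img)
        g = self.apply_L_space(state.v) + (self.restrict(img_f) if self.is_bl else img_f)
        state.gradient = g
        return g

    def _image_term_variant1(self, state: ObjectiveState) -> np.ndarray:
        flow = state.flow
        psi_disp = solve_deformation(state.v_spatial, self.timegrid, "inverse", flow=flow)
        jac = solve_jacobian(state.v_spatial, self.timegrid, flow=flow)
        lam_coeffs = _prefilter(state.bundle.lambda1.data)
        grad_m = self._grad_m(state)
        acc = np.zeros((self.grid.dim,) + self.grid.shape)
        for n, w in enumerate(self._cc):
            pts = flow._base + psi_disp[n].data * self._scale
            lam_n = jac[n].data * _gather(lam_coeffs, pts)
            acc += w * lam_n * grad_m[n]
        return acc

    def _image_term_variant2(self, state: ObjectiveState) -> np.ndarray:
        flow = state.flow
        dts = self.timegrid.dts
        dphi = self._dphi(state)
        rho = state.bundle.lambda1.data * self._g_vec(state)
        acc = np.zeros_like(rho)
        for n in reversed(range(self.timegrid.n_steps)):
            pre = flow.step_vec_adjoint(rho, n)
            acc += 0.5 * dts[n] * (
                self._mat_t_vec(dphi[n], pre) + self._mat_t_vec(dphi[n + 1], rho)
            )
            rho = pre
        return acc

    # -- incremental (linearized) forward maps ------------------------------

    def incremental_state(self, state: ObjectiveState, dv: Velocity) -> ScalarField:
        """Linearized map dv -> dm(1) through the transport equations
        (incremental state equation with source grad(m) . dv)."""
        dv_sp = self.lift(dv)
        flow = state.flow
        dts = self.timegrid.dts
        grad_m = self._grad_m(state)
        src = [np.sum(gm * dv_sp.data, axis=0) for gm in grad_m]
        dm = np.zeros(self.grid.shape)
        for n in range(self.timegrid.n_steps):
            dm = flow.step(dm, n) - 0.5 * dts[n] * (flow.step(src[n], n) + src[n + 1])
        return ScalarField(self.grid, dm)

    def incremental_deformation(self, state: ObjectiveState, dv: Velocity) -> ScalarField:
        """Linearized map dv -> dm(1) through the incremental deformation
        state equation (Variant II route): dm(1) = (grad I0) o phi(1) . dphi(1)."""
        dv_sp = self.lift(dv)
        flow = state.flow
        dts = self.timegrid.dts
        dphi = self._dphi(state)
        src = [self._mat_vec(J, dv_sp.data) for J in dphi]
        du = np.zeros_like(dv_sp.data)
        for n in range(self.timegrid.n_steps):
            du = flow.step_vec(du, n) - 0.5 * dts[n] * (
                flow.step_vec(src[n], n) + src[n + 1]
            )
        return ScalarField(self.grid, np.sum(self._g_vec(state) * du, axis=0))

    # -- Gauss-Newton Hessian-vector products -------------------------------

    def _require_gn(self):
        if not self.spec.metric.supports_gauss_newton:
            raise ValueError(
                "Gauss-Newton is not available for mutual information "
                "(its incremental adjoint involves an intractably dense "
                "operator); use gradient descent"
            )

    def hvp(self, state: ObjectiveState, dv: Velocity) -> Velocity:
        if self.spec.variant == 1:
            return self.hvp_variant1(state, dv)
        return self.hvp_variant2(state, dv)

    def hvp_variant1(self, state: ObjectiveState, dv: Velocity) -> Velocity:
        self._require_gn()
        flow = state.flow
        dts = self.timegrid.dts
        grad_m = self._grad_m(state)
        dm1 = self.incremental_state(state, dv)
        dlam = state.bundle.gn_operator(dm1).data
        acc = np.zeros((self.grid.dim,) + self.grid.shape)
        for n in reversed(range(self.timegrid.n_steps)):
            pre = flow.step_adjoint(dlam, n)
            acc += 0.5 * dts[n] * (grad_m[n] * pre + grad_m[n + 1] * dlam)
            dlam = pre
        img = VectorField(self.grid, acc)
        return self.apply_L_space(dv) + (self.restrict(img) if self.is_bl else img)

    def hvp_variant2(self, state: ObjectiveState, dv: Velocity) -> Velocity:
        self._require_gn()
        flow = state.flow
        dts = self.timegrid.dts
        dphi = self._dphi(state)
        g = self._g_vec(state)
        dm1 = self.incremental_deformation(state, dv)
        dlam1 = state.bundle.gn_operator(dm1).data
        drho = dlam1 * g
        acc = np.zeros_like(drho)
        for n in reversed(range(self.timegrid.n_steps)):
            pre = flow.step_vec_adjoint(drho, n)
            acc += 0.5 * dts[n] * (
                self._mat_t_vec(dphi[n], pre) + self._mat_t_vec(dphi[n + 1], drho)
            )
            drho = pre
        img = VectorField(self.grid, acc)
        return self.apply_L_space(dv) + (self.restrict(img) if self.is_bl else img)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def evaluate_objective(
    i0: ScalarField, i1: ScalarField, v: Velocity, spec: ProblemSpec
) -> ObjectiveState:
    return RegistrationProblem(i0, i1, spec).objective(v)


def gradient_variant1(prob: RegistrationProblem, state: ObjectiveState) -> Velocity:
    return replace_variant(prob, 1).gradient(state)


def gradient_variant2(prob: RegistrationProblem, state: ObjectiveState) -> Velocity:
    return replace_variant(prob, 2).gradient(state)


def hvp_variant1(prob: RegistrationProblem, state: ObjectiveState, dv: Velocity) -> Velocity:
    return prob.hvp_variant1(state, dv)


def hvp_variant2(prob: RegistrationProblem, state: ObjectiveState, dv: Velocity) -> Velocity:
    return prob.hvp_variant2(state, dv)


def replace_variant(prob: RegistrationProblem, variant: int) -> RegistrationProblem:
    if prob.spec.variant == variant:
        return prob
    out = RegistrationProblem.__new__(RegistrationProblem)
    out.__dict__.update(prob.__dict__)
    out.spec = replace(prob.spec, variant=variant)
    return out
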