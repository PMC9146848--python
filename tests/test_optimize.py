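"""Line search, PCG, optimizer steps, stopping rules, multi-resolution."""

import numpy as np
import pytest

from pdereg.grid import GridSpec, ScalarField, VectorField, include_band, inner, project_band
from pdereg.metrics import MetricSpec
from pdereg.optimize import (
    OptimizerConfig,
    armijo_backtrack,
    gd_step,
    gnk_step,
    multiresolution_run,
    optimize_velocity,
    pcg_solve,
    stopping_check,
)
from pdereg.synth import FixtureSpec, make_pair, presmooth, scale_intensities
from pdereg.variants import ProblemSpec, RegistrationProblem


def _prepped(pair, rng=(0.0, 1.0)):
    i0 = presmooth(scale_intensities(pair.i0, rng), 1.0)
    i1 = presmooth(scale_intensities(pair.i1, rng), 1.0)
    return i0, i1


@pytest.fixture(scope="module")
def ssd_problem(blob_pair):
    i0, i1 = _prepped(blob_pair)
    spec = ProblemSpec(variant=2, metric=MetricSpec("ssd", intensity_range=(0, 1)))
    return RegistrationProblem(i0, i1, spec)


class TestArmijo:
    def test_accepts_full_step_on_easy_descent(self, ssd_problem):
        cfg = OptimizerConfig()
        st = ssd_problem.objective(ssd_problem.zero_velocity())
        g = ssd_problem.gradient(st)
        d = -1.0 * ssd_problem.apply_K_space(g)
        step, new = armijo_backtrack(ssd_problem, st, g, d, cfg)
        assert step > 0 and new.energy < st.energy

    def test_rejects_ascent_direction(self, ssd_problem):
        cfg = OptimizerConfig()
        st = ssd_problem.objective(ssd_problem.zero_velocity())
        g = ssd_problem.gradient(st)
        with pytest.raises(ValueError, match="descent"):
            armijo_backtrack(ssd_problem, st, g, ssd_problem.apply_K_space(g), cfg)

    def test_accepted_steps_decrease_energy(self, ssd_problem):
        _, trace = optimize_velocity(ssd_problem, OptimizerConfig(method="gd", max_outer=6))
        e = np.asarray(trace["energy"])
        assert np.all(np.diff(e) <= 0)


class TestPCG:
    def test_identity_operator_exact_in_one_iteration(self):
        g = GridSpec((8, 8))
        rng = np.random.default_rng(0)
        b = VectorField(g, rng.standard_normal((2, 8, 8)))
        x, info = pcg_solve(lambda w: w, b, lambda w: w, max_iters=5, tol=1e-12)
        assert info["iters"] == 1
        assert np.abs(x.data - b.data).max() <= 1e-12

    def test_matches_dense_solve_on_small_spd_system(self):
        """Band-limited coefficients (dim <= 512) against numpy.linalg.solve."""
        g = GridSpec((8, 8))
        rng = np.random.default_rng(1)
        bounds = (4, 4)
        proto = project_band(VectorField(g, rng.standard_normal((2, 8, 8))), bounds)

        # SPD operator: K-preconditioned metric operator L in the band plus
        # a low-rank PSD perturbation assembled from lifted products
        from pdereg.grid import RegularizerSpec, apply_L_bl

        spec = RegularizerSpec()
        u = project_band(VectorField(g, rng.standard_normal((2, 8, 8))), bounds)

        def op(w):
            return apply_L_bl(w, spec) + inner(u, w) * u

        b = project_band(VectorField(g, rng.standard_normal((2, 8, 8))), bounds)
        x, info = pcg_solve(op, b, lambda w: w, max_iters=200, tol=1e-14)
        # dense oracle over the real/imag coefficient coordinates
        box = proto.coeffs.shape
        n = int(np.prod(box))

        def from_vec(z):
            from pdereg.grid import BandLimitedField
            return BandLimitedField(bounds, (z[:n] + 1j * z[n:]).reshape(box))

        def to_vec(w):
            return np.concatenate([w.coeffs.real.ravel(), w.coeffs.imag.ravel()])

        dim = 2 * n
        A = np.zeros((dim, dim))
        for j in range(dim):
            e = np.zeros(dim)
            e[j] = 1.0
            A[:, j] = to_vec(op(from_vec(e)))
        # Hermitian projection makes the basis overcomplete; solve in the
        # range of the projection with lstsq
        sol, *_ = np.linalg.lstsq(A, to_vec(b), rcond=None)
        x_dense = from_vec(sol)
        assert np.abs(x.coeffs - x_dense.coeffs).max() <= 1e-8

    def test_residuals_non_increasing(self, ssd_problem):
        st = ssd_problem.objective(ssd_problem.zero_velocity())
        g = ssd_problem.gradient(st)
        _, info = pcg_solve(
            lambda w: ssd_problem.hvp(st, w), -1.0 * g,
            ssd_problem.apply_K_space, max_iters=5, tol=0.0,
        )
        res = info["residuals"]
        assert all(b <= a + 1e-12 for a, b in zip(res, res[1:]))

    def test_zero_rhs(self):
        g = GridSpec((8, 8))
        z = VectorField.zeros(g)
        x, info = pcg_solve(lambda w: w, z, lambda w: w)
        assert info["iters"] == 0 and np.abs(x.data).max() == 0.0


class TestSteps:
    def test_gd_zero_gradient_no_move(self, blob_pair):
        i0, _ = _prepped(blob_pair)
        spec = ProblemSpec(variant=2, metric=MetricSpec("ssd", intensity_range=(0, 1)))
        prob = RegistrationProblem(i0, i0, spec)
        st = prob.objective(prob.zero_velocity())
        st.gradient = prob.zero_velocity()  # exactly-zero gradient contract
        step, new_state, grad = gd_step(prob, st, OptimizerConfig(method="gd"))
        assert step == 0.0 and new_state is st

    def test_single_gd_step_reduces_similarity(self, ssd_problem):
        st = ssd_problem.objective(ssd_problem.zero_velocity())
        _, new_state, _ = gd_step(ssd_problem, st, OptimizerConfig(method="gd"))
        assert new_state.e_img < st.e_img

    def test_preconditioned_step_approaches_plain_in_alpha_zero_limit(self, blob_pair):
        from pdereg.grid import RegularizerSpec, apply_K

        i0, i1 = _prepped(blob_pair)
        spec = ProblemSpec(
            variant=2, metric=MetricSpec("ssd", intensity_range=(0, 1)),
            regularizer=RegularizerSpec(alpha=1e-12, s=2),
        )
        prob = RegistrationProblem(i0, i1, spec)
        st = prob.objective(prob.zero_velocity())
        g = prob.gradient(st)
        kg = apply_K(g, spec.regularizer)
        assert np.abs(kg.data - g.data).max() <= 1e-8 * np.abs(g.data).max()

    def test_gnk_beats_gd_from_same_state(self, ssd_problem):
        cfg = OptimizerConfig()
        st = ssd_problem.objective(ssd_problem.zero_velocity())
        _, gd_state, _ = gd_step(ssd_problem, st, OptimizerConfig(method="gd"))
        _, gnk_state, _, _ = gnk_step(ssd_problem, st, cfg)
        assert gnk_state.energy < gd_state.energy

    def test_gnk_refuses_mi(self, blob_pair):
        i0, i1 = _prepped(blob_pair, (0.0, 255.0))
        spec = ProblemSpec(variant=2, metric=MetricSpec("mi"))
        prob = RegistrationProblem(i0, i1, spec)
        st = prob.objective(prob.zero_velocity())
        with pytest.raises(ValueError, match="[Mm]utual information"):
            gnk_step(prob, st, OptimizerConfig())


class TestStopping:
    def test_zero_gradient_stops(self):
        assert stopping_check(0.0, [1.0], OptimizerConfig()) == "gradient"

    def test_flat_energy_stops(self):
        cfg = OptimizerConfig()
        assert stopping_check(1.0, [1.0, 1.0 - 1e-9, 1.0 - 2e-9], cfg) == "energy"

    def test_no_stop_while_progressing(self):
        cfg = OptimizerConfig()
        assert stopping_check(0.5, [1.0, 0.5, 0.25], cfg) is None

    def test_converged_run_stops_before_budget(self, ssd_problem):
        _, trace = optimize_velocity(ssd_problem, OptimizerConfig(method="gnk"))
        assert trace["stop_reason"] in ("gradient", "energy")
        assert len(trace["energy"]) - 1 < 10

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            OptimizerConfig(method="newton")
        with pytest.raises(ValueError):
            OptimizerConfig(pcg_iters=0)
        with pytest.raises(ValueError):
            OptimizerConfig(armijo_c=1.5)


class TestEndToEnd:
    @pytest.mark.parametrize("kind,rng", [("ssd", (0.0, 1.0)), ("ncc", (0.0, 1.0))])
    def test_gnk_recovers_within_ten_iterations(self, blob_pair, kind, rng):
        from pdereg.evaluate import mse_rel

        i0, i1 = _prepped(blob_pair, rng)
        spec = ProblemSpec(variant=2, metric=MetricSpec(kind, intensity_range=rng))
        prob = RegistrationProblem(i0, i1, spec)
        st, trace = optimize_velocity(prob, OptimizerConfig(method="gnk"))
        assert len(trace["energy"]) - 1 <= 10
        assert mse_rel(ScalarField(i0.grid, st.m[-1]), i0, i1) <= 10.0

    def test_positive_jacobian_after_convergence(self, blob_pair):
        i0, i1 = _prepped(blob_pair)
        spec = ProblemSpec(variant=2, metric=MetricSpec("ssd", intensity_range=(0, 1)))
        res = multiresolution_run(i0, i1, spec, OptimizerConfig(method="gnk"))
        assert res.jac_min > 0


class TestMultiResolution:
    def test_single_level_equals_direct_run(self, blob_pair):
        i0, i1 = _prepped(blob_pair)
        spec = ProblemSpec(variant=2, metric=MetricSpec("ssd", intensity_range=(0, 1)))
        cfg = OptimizerConfig(method="gnk", max_outer=3)
        res = multiresolution_run(i0, i1, spec, cfg)
        prob = RegistrationProblem(i0, i1, spec)
        st, trace = optimize_velocity(prob, cfg)
        assert np.allclose(res.energy_trace, trace["energy"])
        assert np.abs(res.v.data - st.v.data).max() <= 1e-14

    def test_velocity_upsample_round_trip(self):
        from pdereg.optimize import _upsample_velocity

        coarse, fine = GridSpec((16, 16)), GridSpec((32, 32))
        rng = np.random.default_rng(3)
        v = include_band(project_band(
            VectorField(coarse, rng.standard_normal((2, 16, 16))), (8, 8)), coarse)
        spec = ProblemSpec(variant=2, metric=MetricSpec("ssd"))
        up = _upsample_velocity(v, coarse, fine, spec)
        down = include_band(project_band(up, coarse.shape), coarse)
        assert np.abs(down.data - v.data).max() <= 1e-12

    def test_too_many_levels_rejected(self, blob_pair):
        i0, i1 = _prepped(blob_pair)
        spec = ProblemSpec(variant=2, metric=MetricSpec("ssd", intensity_range=(0, 1)))
        with pytest.raises(ValueError, match="levels"):
            multiresolution_run(i0, i1, spec, OptimizerConfig(levels=6))

    def test_multiresolution_beats_single_on_large_displacement(self):
        """15-voxel displacements on a structured template: the pyramid
        escapes the local minimum the single-resolution solve lands in."""
        pair = make_pair(FixtureSpec(
            seed=3, template="checker_organ", velocity_amplitude=20.0, velocity_band=4))
        i0 = presmooth(scale_intensities(pair.i0, (0, 1)), 1.0)
        i1 = presmooth(scale_intensities(pair.i1, (0, 1)), 1.0)
        spec = ProblemSpec(variant=2, metric=MetricSpec("ssd", intensity_range=(0, 1)))
        res1 = multiresolution_run(i0, i1, spec, OptimizerConfig(method="gnk", levels=1))
        res3 = multiresolution_run(i0, i1, spec, OptimizerConfig(method="gnk", levels=3))
        assert res3.e_img_trace[-1] < res1.e_img_trace[-1]
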