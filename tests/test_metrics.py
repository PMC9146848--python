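"""Similarity metrics: values, adjoints (finite-difference oracles),
Gauss-Newton operators (PSD + second-order behavior), Parzen densities."""

import itertools

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, uniform_filter

from pdereg.grid import GridSpec, ScalarField
from pdereg.metrics import (
    MetricSpec,
    lncc_bundle,
    metric_bundle,
    mi_bundle,
    ncc_bundle,
    ngf_bundle,
    parzen_joint,
    ssd_bundle,
    _parzen_coords,
)

G = GridSpec((32, 32))

# metric name -> (intensity range used by convention, FD tolerance)
CASES = {
    "ssd": ((0.0, 1.0), 1e-6),
    "ncc": ((0.0, 1.0), 1e-5),
    "lncc": ((0.0, 255.0), 1e-4),
    "ngf": ((0.0, 255.0), 1e-4),
    "mi": ((0.0, 255.0), 1e-3),
}


def _img(seed, rng, sig=2.5, margin=0.02):
    """Smooth image valued strictly inside the declared range (the MI bin
    mapping clamps at the exact bounds, where E is one-sided-differentiable)."""
    r = np.random.default_rng(seed)
    a = gaussian_filter(r.standard_normal(G.shape), sig, mode="wrap")
    a = (a - a.min()) / (a.max() - a.min())
    lo = rng[0] + margin * (rng[1] - rng[0])
    hi = rng[1] - margin * (rng[1] - rng[0])
    return ScalarField(G, lo + a * (hi - lo))


def _direction(seed):
    d = gaussian_filter(np.random.default_rng(seed).standard_normal(G.shape), 1.5, mode="wrap")
    return d / np.abs(d).max()


@pytest.mark.parametrize("kind", list(CASES))
def test_lambda1_matches_finite_difference(kind):
    rng, tol = CASES[kind]
    spec = MetricSpec(kind, intensity_range=rng)
    m1, i1 = _img(1, rng), _img(2, rng)
    bun = metric_bundle(m1, i1, spec)
    eps = 1e-5 * (rng[1] - rng[0])
    for k in range(5):
        dm = _direction(50 + k)
        ep = metric_bundle(ScalarField(G, m1.data + eps * dm), i1, spec).value
        em = metric_bundle(ScalarField(G, m1.data - eps * dm), i1, spec).value
        fd = (ep - em) / (2 * eps)
        an = -float(np.mean(bun.lambda1.data * dm))
        assert abs(fd - an) <= tol * max(abs(fd), 1e-9)


@pytest.mark.parametrize("kind", ["ssd", "ncc", "lncc", "ngf"])
def test_gauss_newton_negative_semidefinite(kind):
    rng, _ = CASES[kind]
    spec = MetricSpec(kind, intensity_range=rng)
    bun = metric_bundle(_img(1, rng), _img(2, rng), spec)
    for k in range(20):
        dm = np.random.default_rng(100 + k).standard_normal(G.shape)
        quad = -float(np.mean(dm * bun.gn_operator(ScalarField(G, dm)).data))
        assert quad >= -1e-10


@pytest.mark.parametrize("kind", ["ssd", "ncc", "lncc"])
def test_gauss_newton_matches_hessian_at_small_residual(kind):
    """Near m = I the GN operator is the true differential of lambda(1)."""
    rng, _ = CASES[kind]
    spec = MetricSpec(kind, intensity_range=rng)
    i1 = _img(2, rng)
    scale = rng[1] - rng[0]
    m1 = ScalarField(G, i1.data + 0.02 * scale * _direction(7))
    bun = metric_bundle(m1, i1, spec)
    dm = _direction(11)
    eps = 1e-3 * scale
    lp = metric_bundle(ScalarField(G, m1.data + eps * dm), i1, spec).lambda1.data
    lm = metric_bundle(ScalarField(G, m1.data - eps * dm), i1, spec).lambda1.data
    dl_fd = (lp - lm) / (2 * eps)
    dl_gn = bun.gn_operator(ScalarField(G, dm)).data
    assert np.abs(dl_gn - dl_fd).max() <= 0.05 * np.abs(dl_fd).max()


class TestSSD:
    def test_identical_images(self):
        m = _img(1, (0, 1))
        bun = ssd_bundle(m, m, MetricSpec("ssd"))
        assert bun.value == 0.0
        assert np.abs(bun.lambda1.data).max() == 0.0

    def test_closed_form_offset(self):
        i1 = _img(2, (0, 1))
        m1 = ScalarField(G, i1.data + 0.5)
        bun = ssd_bundle(m1, i1, MetricSpec("ssd", sigma2=1.0))
        assert np.allclose(bun.lambda1.data, -1.0)
        assert np.isclose(bun.value, 0.25)

    def test_grid_mismatch_rejected(self):
        other = GridSpec((16, 16))
        with pytest.raises(ValueError):
            ssd_bundle(_img(1, (0, 1)), ScalarField(other, np.zeros((16, 16))), MetricSpec("ssd"))


class TestNCC:
    def test_identical_and_sign_flipped(self):
        m = _img(1, (0, 1))
        spec = MetricSpec("ncc", intensity_range=(0, 1))
        bun = ncc_bundle(m, m, spec)
        assert abs(bun.value) <= 1e-12
        assert np.abs(bun.lambda1.data).max() <= 1e-12
        flipped = ScalarField(G, -m.data + 3.0)
        assert abs(ncc_bundle(flipped, m, spec).value) <= 1e-12

    def test_affine_intensity_invariance(self):
        m, i1 = _img(1, (0, 1)), _img(2, (0, 1))
        spec = MetricSpec("ncc", intensity_range=(0, 1))
        v0 = ncc_bundle(m, i1, spec).value
        v1 = ncc_bundle(ScalarField(G, 2.5 * m.data + 0.3), i1, spec).value
        assert abs(v0 - v1) <= 1e-12

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            ncc_bundle(ScalarField(G, np.ones(G.shape)), _img(2, (0, 1)), MetricSpec("ncc"))


class TestLNCC:
    SPEC = MetricSpec("lncc", lncc_radius=4, intensity_range=(0, 255))

    def test_identical_images(self):
        m = _img(1, (0, 255))
        assert abs(lncc_bundle(m, m, self.SPEC).value) <= 1e-10

    def test_local_affine_invariance(self):
        m = _img(1, (0, 255))
        remapped = ScalarField(G, 1.7 * m.data + 12.0)
        assert abs(lncc_bundle(remapped, m, self.SPEC).value) <= 1e-10

    def test_window_larger_than_image_rejected(self):
        g8 = GridSpec((8, 8))
        img = ScalarField(g8, np.random.default_rng(0).uniform(0, 255, (8, 8)))
        with pytest.raises(ValueError):
            lncc_bundle(img, img, MetricSpec("lncc", lncc_radius=4))

    def test_gn_matches_brute_force_residual_form(self):
        """<dm, -gn(dm)>/2 equals ||J dm||^2 of the per-window residual."""
        g = GridSpec((16, 16))
        r = np.random.default_rng(5)
        nu = 2
        spec = MetricSpec("lncc", lncc_radius=nu)
        m = 5 + 245 * r.uniform(size=g.shape)
        i1 = 5 + 245 * r.uniform(size=g.shape)
        bun = lncc_bundle(ScalarField(g, m), ScalarField(g, i1), spec)
        P = lambda a: uniform_filter(a, size=2 * nu + 1, mode="wrap")
        mu_i = P(i1)
        Cf = np.maximum(P(i1 * i1) - mu_i**2, 1e-10 * (P(i1 * i1) - mu_i**2).max())

        def resid_field(mm):
            mu = P(mm)
            B = P(mm * mm) - mu**2
            Bf = np.maximum(B, 1e-10 * B.max())
            A = P(mm * i1) - mu * mu_i
            rho = A / np.sqrt(Bf * Cf)
            out = []
            for ox, oy in itertools.product(range(-nu, nu + 1), repeat=2):
                ms = np.roll(mm, (-ox, -oy), axis=(0, 1))
                Is = np.roll(i1, (-ox, -oy), axis=(0, 1))
                out.append((ms - mu) / np.sqrt(Bf) - rho * (Is - mu_i) / np.sqrt(Cf))
            return np.stack(out)

        dm = gaussian_filter(r.standard_normal(g.shape), 1.0, mode="wrap")
        eps = 1e-4 * 255
        jdm = (resid_field(m + eps * dm) - resid_field(m - eps * dm)) / (2 * eps)
        q_oracle = float(np.mean(jdm**2))
        q_impl = -0.5 * float(np.mean(dm * bun.gn_operator(ScalarField(g, dm)).data))
        assert abs(q_impl - q_oracle) <= 1e-5 * q_oracle


class TestNGF:
    SPEC = MetricSpec("ngf", intensity_range=(0, 255))

    def test_identical_images(self):
        m = _img(1, (0, 255))
        assert abs(ngf_bundle(m, m, self.SPEC).value) <= 1e-12

    def test_orthogonal_gradients_limit(self):
        # grad m along x, grad I along y, eps^2 -> 0: value -> |Omega|/sigma^2
        x, y = G.coords()
        m1 = ScalarField(G, 100 * np.sin(2 * np.pi * x) + 120)
        i1 = ScalarField(G, 100 * np.sin(2 * np.pi * y) + 120)
        val = ngf_bundle(m1, i1, MetricSpec("ngf", ngf_eps2=1e-8)).value
        # r = 1 on the measure-zero set where both gradients vanish
        # (4 grid points here), so the limit is 1 - 4/nvox
        assert abs(val - 1.0) <= 5e-3

    def test_scale_invariance_with_matched_eps(self):
        # scaling both images by a and eps^2 by a^2 leaves r, hence E, unchanged
        m, i1 = _img(1, (0, 255)), _img(2, (0, 255))
        v0 = ngf_bundle(m, i1, MetricSpec("ngf", ngf_eps2=1000.0)).value
        v2 = ngf_bundle(
            ScalarField(G, 3.0 * m.data),
            ScalarField(G, 3.0 * i1.data),
            MetricSpec("ngf", ngf_eps2=9 * 1000.0),
        ).value
        assert abs(v0 - v2) <= 1e-10


class TestParzenMI:
    SPEC = MetricSpec("mi", intensity_range=(0, 255))

    def test_joint_normalization_and_marginals(self):
        m, i1 = _img(1, (0, 255)), _img(2, (0, 255))
        p, p_m, p_i = parzen_joint(m, i1, self.SPEC)
        assert abs(p.sum() - 1.0) <= 1e-12
        assert np.allclose(p.sum(axis=1), p_m) and np.allclose(p.sum(axis=0), p_i)

    def test_brute_force_oracle_8x8(self):
        g8 = GridSpec((8, 8))
        r = np.random.default_rng(9)
        ma = ScalarField(g8, r.uniform(0, 255, (8, 8)))
        ia = ScalarField(g8, r.uniform(0, 255, (8, 8)))
        p, _, _ = parzen_joint(ma, ia, self.SPEC)

        def xi(u):
            au = np.abs(u)
            return np.where(
                au < 1, 2 / 3 - au**2 + au**3 / 2,
                np.where(au < 2, (2 - au) ** 3 / 6, 0.0),
            )

        tm, _ = _parzen_coords(ma.data, self.SPEC)
        ti, _ = _parzen_coords(ia.data, self.SPEC)
        brute = np.zeros((16, 16))
        for rr, ss in itertools.product(range(16), repeat=2):
            brute[rr, ss] = np.mean(xi(rr - tm) * xi(ss - ti))
        assert np.abs(p - brute).max() <= 1e-14

    def test_constant_pair_degenerate(self):
        c = ScalarField(G, np.full(G.shape, 128.0))
        with pytest.raises(ValueError):
            parzen_joint(c, c, self.SPEC)

    def test_symmetry(self):
        a, b = _img(1, (0, 255)), _img(2, (0, 255))
        assert abs(mi_bundle(a, b, self.SPEC).value - mi_bundle(b, a, self.SPEC).value) <= 1e-12

    def test_self_mi_close_to_entropy_up_to_parzen_smear(self):
        m = _img(1, (0, 255))
        bun = mi_bundle(m, m, self.SPEC)
        _, p_m, _ = parzen_joint(m, m, self.SPEC)
        h = -float(np.sum(p_m[p_m > 0] * np.log(p_m[p_m > 0])))
        mi_self = -bun.value  # sigma2 = 1
        bias = h - mi_self
        assert 0.0 <= bias <= np.log(7.0)
        assert mi_self > 0.4 * h

    def test_independent_images_near_zero(self):
        g = GridSpec((64, 64))
        r = np.random.default_rng(11)
        a = ScalarField(g, r.uniform(0, 255, g.shape))
        b = ScalarField(g, r.uniform(0, 255, g.shape))
        assert abs(mi_bundle(a, b, self.SPEC).value) <= 0.02

    def test_no_gauss_newton_operator(self):
        m, i1 = _img(1, (0, 255)), _img(2, (0, 255))
        assert mi_bundle(m, i1, self.SPEC).gn_operator is None
        assert not self.SPEC.supports_gauss_newton


def test_metric_spec_validation():
    with pytest.raises(ValueError):
        MetricSpec("nope")
    with pytest.raises(ValueError):
        MetricSpec("ssd", sigma2=0.0)
    with pytest.raises(ValueError):
        MetricSpec("mi", mi_bins=1)
    with pytest.raises(ValueError):
        MetricSpec("lncc", lncc_radius=0)
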