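"""Green's-function propagator, continuum fields, and the moment algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from flipkin import (
    DeltaIC,
    GaussianIC,
    GreensKernel,
    MixtureIC,
    equilibrium_continuum,
    f_of_v,
    green,
    mean_u,
    moments_of_field,
    propagate,
    second_moment_u,
    sigma,
)
from flipkin.errors import DegenerateDeltaError, ParameterError
from flipkin.fokker_planck import (
    GriddedField,
    to_uv,
    to_xz,
    uv_to_xz,
    v_moment,
    xz_to_uv,
)

LN2 = math.log(2.0)


class TestSigma:
    def test_zero_at_zero_and_saturates(self, ex2_params):
        assert sigma(0.0, ex2_params) == 0.0
        assert sigma(1e3, ex2_params) == pytest.approx(800 / 9, rel=1e-12)

    def test_three_quarters_at_ln2(self, ex2_params):
        assert sigma(LN2, ex2_params) == pytest.approx(0.75 * 800 / 9, rel=1e-12)

    def test_strictly_increasing(self, ex2_params):
        t = np.linspace(0, 5, 200)
        assert np.all(np.diff(sigma(t, ex2_params)) > 0)

    def test_negative_time_rejected(self, ex2_params):
        with pytest.raises(ParameterError):
            sigma(-0.1, ex2_params)


class TestGreen:
    def test_normalized_over_u(self, ex2_params, rng):
        for _ in range(5):
            v, up, t = rng.uniform(50, 150), rng.uniform(-60, 60), rng.uniform(0.05, 3)
            val, _ = quad(lambda u: green(u, v, t, up, ex2_params), -400, 400, epsabs=1e-12)
            assert val == pytest.approx(1.0, abs=1e-10)

    def test_first_moment_identity(self, ex2_params, rng):
        """integral u G du equals the kernel mean u' E + v r (1-E)."""
        k = GreensKernel(ex2_params)
        for _ in range(3):
            v, up, t = rng.uniform(60, 140), rng.uniform(-50, 50), rng.uniform(0.1, 2)
            val, _ = quad(lambda u: u * green(u, v, t, up, ex2_params), -500, 500)
            E = math.exp(-t)
            assert val == pytest.approx(up * E + v * (1 / 3) * (1 - E), rel=1e-9)
            assert k.mu(v, t, up) == pytest.approx(up * E + v * (1 / 3) * (1 - E))

    def test_long_time_limit_forgets_start(self, ex2_params):
        u = np.linspace(-20, 80, 11)
        a = green(u, 100.0, 60.0, -70.0, ex2_params)
        b = green(u, 100.0, 60.0, +70.0, ex2_params)
        np.testing.assert_allclose(a, b, rtol=1e-12)
        k = GreensKernel(ex2_params)
        assert k.mu(100.0, 60.0, -70.0) == pytest.approx(100 / 3, rel=1e-12)

    def test_zero_time_is_degenerate(self, ex2_params):
        with pytest.raises(DegenerateDeltaError):
            green(0.0, 100.0, 0.0, 0.0, ex2_params)


class TestPropagate:
    def test_time_zero_is_identity(self, ex2_params):
        ic = GaussianIC(100 / 3, 200 / 3)
        fld = propagate(ic, 0.0, ex2_params)
        u = np.linspace(-80, 40, 7)
        np.testing.assert_allclose(
            fld.density_uv(u, 100.0), ic.to_field(ex2_params).density_uv(u, 100.0)
        )

    def test_long_time_reaches_equilibrium_of_f(self, ex2_params):
        """propagate(ic, t->inf) equals the equilibrium built from f(v) alone."""
        ic = MixtureIC((0.4, 0.6), (25.0, 30.0), (60.0, 80.0))
        late = propagate(ic, 40.0, ex2_params)
        eq = equilibrium_continuum(f_of_v(ic, ex2_params), ex2_params)
        U, V = np.meshgrid(np.linspace(-60, 120, 40), np.linspace(60, 140, 40), indexing="ij")
        a, b = late.density_uv(U, V), eq.density_uv(U, V)
        assert np.abs(a - b).max() <= 1e-8 * b.max()

    def test_equilibrium_is_stationary_under_propagation(self, ex2_params):
        eq = equilibrium_continuum(f_of_v(GaussianIC(100 / 3, 200 / 3), ex2_params), ex2_params)
        moved = propagate(eq, 1.7, ex2_params)
        U, V = np.meshgrid(np.linspace(-40, 120, 30), np.linspace(60, 140, 30), indexing="ij")
        np.testing.assert_allclose(moved.density_uv(U, V), eq.density_uv(U, V), rtol=1e-10)

    def test_chapman_kolmogorov_semigroup(self, ex2_params):
        """Propagating to t1 then t2-t1 equals propagating straight to t2."""
        ic = GaussianIC(100 / 3, 200 / 3)
        one = propagate(propagate(ic, 0.4, ex2_params), 0.9, ex2_params)
        two = propagate(ic, 1.3, ex2_params)
        for ca, cb in zip(one.components, two.components):
            np.testing.assert_allclose(ca.mean, cb.mean, rtol=1e-12)
            np.testing.assert_allclose(ca.cov, cb.cov, rtol=1e-12)

    def test_gridded_propagation_matches_closed_form(self, ex2_params):
        """Per-v-slice trapezoid convolution reproduces the Gaussian algebra."""
        ic = GaussianIC(100 / 3, 200 / 3)
        fld0 = ic.to_field(ex2_params)
        u = np.linspace(-150, 120, 541)
        v = np.linspace(40, 160, 121)
        grid0 = GriddedField.from_function(fld0.density_uv, u, v, ex2_params)
        out = propagate(grid0, LN2)
        ref = propagate(ic, LN2, ex2_params)
        U, V = np.meshgrid(u[100:-100], v[20:-20], indexing="ij")
        a = out.density_uv(U, V)
        b = ref.density_uv(U, V)
        assert np.abs(a - b).max() <= 1e-5 * b.max()
        assert out.carriers() == pytest.approx(ex2_params.N, rel=1e-8)


class TestFOfV:
    def test_gaussian_start_gives_gaussian_total_load(self, ex2_params):
        """f(v) = 2N Normal(v; M/N, M/N) for the variance=mean product start."""
        f = f_of_v(GaussianIC(100 / 3, 200 / 3), ex2_params)
        v = np.linspace(60, 140, 9)
        expect = 2 * 100 * np.exp(-((v - 100.0) ** 2) / 200.0) / np.sqrt(2 * np.pi * 100)
        np.testing.assert_allclose(f(v), expect, rtol=1e-12)
        assert f.mass == pytest.approx(2 * ex2_params.N)

    def test_delta_start_gives_delta_total_load(self, ex2_params):
        f = f_of_v(DeltaIC(100.0, 100.0), ex2_params)
        assert f.components == [(2 * ex2_params.N, 100.0, 0.0)]
        with pytest.raises(DegenerateDeltaError):
            f(100.0)

    def test_f_is_conserved_under_propagation(self, ex2_params):
        ic = MixtureIC((0.5, 0.5), (20.0, 40.0), (60.0, 80.0))
        f0 = f_of_v(ic, ex2_params)
        ft = propagate(ic, 0.8, ex2_params).f_of_v()
        v = np.linspace(50, 150, 21)
        np.testing.assert_allclose(ft(v), f0(v), rtol=1e-12)


class TestMoments:
    def test_mean_u_matches_first_moment_kinetics(self, ex2_params):
        from flipkin import first_moments_analytic

        t = np.linspace(0, 4, 17)
        mu = mean_u(t, 100 / 3, 200 / 3, ex2_params)
        ME, MI = first_moments_analytic(t, 100 / 3, 200 / 3, ex2_params)
        np.testing.assert_allclose(mu, ME - MI, rtol=1e-12)

    def test_delta_start_mean(self, ex2_params):
        """All-external start: <u> = muE - muI (1 - 2 e^{-t/tau})."""
        t = np.linspace(0, 4, 9)
        expect = ex2_params.muE - ex2_params.muI * (1 - 2 * np.exp(-t))
        np.testing.assert_allclose(mean_u(t, 100.0, 0.0, ex2_params), expect, rtol=1e-12)

    def test_second_moment_long_time_limit(self, ex2_params):
        m2v0 = 10100.0
        out = second_moment_u(1e3, 10900 / 9, -10100 / 3, m2v0, ex2_params)
        assert out == pytest.approx(800 / 9 + (1 / 9) * m2v0, rel=1e-12)

    def test_variance_dip_from_moment_algebra(self, ex2_params):
        """var_u = <u^2> - <u>^2 dips to (8/9) M/N at t = tau ln 2."""
        t = np.linspace(0.0, 4.0, 2001)
        m2 = second_moment_u(t, 10900 / 9, -10100 / 3, 10100.0, ex2_params)
        var = m2 - mean_u(t, 100 / 3, 200 / 3, ex2_params) ** 2
        k = var.argmin()
        assert var[k] == pytest.approx((8 / 9) * 100, rel=1e-6)
        assert abs(t[k] - LN2) < 2e-3

    def test_moment_formulas_match_quadrature_of_propagated_field(self, ex2_params, rng):
        """The closed-form moment algebra equals 2-D quadrature on the grid."""
        for _ in range(3):
            etaE = rng.uniform(20, 60)
            etaI = 100.0 - etaE
            ic = GaussianIC(etaE, etaI)
            t = rng.uniform(0.2, 1.5)
            fld = propagate(ic, t, ex2_params)
            u = np.linspace(-250, 250, 801)
            v = np.linspace(20, 180, 401)
            grid = GriddedField.from_function(fld.density_uv, u, v, ex2_params, t=t)
            rec = moments_of_field(grid)
            m2u0 = (etaE + etaI) + (etaE - etaI) ** 2
            m11_0 = (etaE - etaI) * (1 + etaE + etaI)
            m2v0 = (etaE + etaI) + (etaE + etaI) ** 2
            assert rec.mean_u == pytest.approx(mean_u(t, etaE, etaI, ex2_params), abs=1e-8 * 100)
            assert rec.m2_u == pytest.approx(
                second_moment_u(t, m2u0, m11_0, m2v0, ex2_params), rel=1e-8
            )
            assert rec.mean_v == pytest.approx(100.0, rel=1e-8)

    def test_mean_v_and_v_moments_conserved(self, ex2_params):
        """<v> = M/N and raw v-moments up to order 4 never change."""
        ic = MixtureIC((0.5, 0.5), (10.0, 50.0), (80.0, 60.0))
        f0 = ic.to_field(ex2_params)
        for t in (0.3, 1.1, 6.0):
            ft = propagate(ic, t, ex2_params)
            assert moments_of_field(ft).mean_v == pytest.approx(
                ic.mean_loads(ex2_params)[0] + ic.mean_loads(ex2_params)[1], rel=1e-12
            )
            for k in (1, 2, 3, 4):
                assert v_moment(ft, k) == pytest.approx(v_moment(f0, k), rel=1e-12)

    def test_equilibrium_second_moment_depends_on_initial_v_spread(self, ex2_params):
        """Two starts with different <v^2>_0 reach different equilibria."""
        narrow = DeltaIC(100.0 / 3 * -1, 100.0)  # delta in v: <v^2>_0 = (M/N)^2
        wide = GaussianIC(100 / 3, 200 / 3)  # <v^2>_0 = M/N + (M/N)^2
        eq_n = moments_of_field(propagate(narrow, 80.0, ex2_params))
        eq_w = moments_of_field(propagate(wide, 80.0, ex2_params))
        assert eq_n.m2_u == pytest.approx(800 / 9 + (1 / 9) * 100**2, rel=1e-9)
        assert eq_w.m2_u == pytest.approx(800 / 9 + (1 / 9) * 10100, rel=1e-9)


class TestEquilibriumContinuum:
    def test_gaussian_f_gives_product_gaussian_in_xz(self, ex2_params):
        """The equilibrium of the Gaussian start factorizes as
        Normal(x; muE, muE) * Normal(z; muI, muI)."""
        eq = equilibrium_continuum(f_of_v(GaussianIC(100 / 3, 200 / 3), ex2_params), ex2_params)
        exz = to_xz(eq)
        (c,) = exz.components
        np.testing.assert_allclose(c.mean, [200 / 3, 100 / 3], rtol=1e-12)
        np.testing.assert_allclose(
            c.cov, [[200 / 3, 0.0], [0.0, 100 / 3]], atol=1e-10
        )

    def test_same_f_same_equilibrium(self, ex2_params):
        """Equal v-marginals force equal equilibria regardless of the u-split."""
        a = equilibrium_continuum(f_of_v(GaussianIC(100 / 3, 200 / 3), ex2_params), ex2_params)
        b = equilibrium_continuum(f_of_v(GaussianIC(60.0, 40.0), ex2_params), ex2_params)
        U, V = np.meshgrid(np.linspace(-50, 110, 21), np.linspace(60, 140, 21), indexing="ij")
        np.testing.assert_allclose(a.density_uv(U, V), b.density_uv(U, V), rtol=1e-12)

    def test_callable_f_on_grid(self, ex2_params):
        f = f_of_v(GaussianIC(100 / 3, 200 / 3), ex2_params)
        u = np.linspace(-100, 150, 301)
        v = np.linspace(40, 160, 201)
        eq_grid = equilibrium_continuum(f.__call__, ex2_params, grid=(u, v))
        eq_mix = equilibrium_continuum(f, ex2_params)
        U, V = np.meshgrid(u[50:-50], v[40:-40], indexing="ij")
        np.testing.assert_allclose(
            eq_grid.density_uv(U, V), eq_mix.density_uv(U, V), rtol=1e-9
        )
        assert eq_grid.carriers() == pytest.approx(ex2_params.N, rel=1e-8)


class TestCharts:
    @given(x=st.floats(-50, 200), z=st.floats(-50, 200))
    @settings(max_examples=100, derandomize=True)
    def test_coordinate_round_trip(self, x, z):
        u, v = xz_to_uv(x, z)
        x2, z2 = uv_to_xz(u, v)
        assert x2 == pytest.approx(x, abs=1e-12)
        assert z2 == pytest.approx(z, abs=1e-12)

    def test_field_round_trip_and_value_invariance(self, ex2_params, rng):
        fld = propagate(GaussianIC(100 / 3, 200 / 3), 0.7, ex2_params)
        back = to_uv(to_xz(fld))
        for ca, cb in zip(fld.components, back.components):
            np.testing.assert_allclose(ca.mean, cb.mean, rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(ca.cov, cb.cov, rtol=1e-12, atol=1e-12)
        x, z = rng.uniform(20, 80, 5), rng.uniform(10, 60, 5)
        np.testing.assert_allclose(
            to_xz(fld).density_xz(x, z), fld.density_xz(x, z), rtol=1e-12
        )

    def test_carrier_count_preserved_across_charts(self, ex2_params):
        fld = propagate(GaussianIC(100 / 3, 200 / 3), 0.7, ex2_params)
        # (1/2) integral over (u,v) == integral over (x,z) == N
        u = np.linspace(-200, 200, 801)
        v = np.linspace(20, 180, 401)
        g = GriddedField.from_function(fld.density_uv, u, v, ex2_params)
        assert g.carriers() == pytest.approx(ex2_params.N, rel=1e-8)
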