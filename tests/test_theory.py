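"""PB cell model, strong-coupling/needle references, onset formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cylcond as cc
from cylcond.theory import FreeEnergyDifference, free_energy_difference


class TestPBSolution:
    def test_gauss_law_boundaries(self):
        for xi in (0.5, 1.0, 2.0, 5.0):
            sol = cc.pb_solve(xi, 8.0)
            assert sol.condensed_fraction_at(1.0) == pytest.approx(0.0, abs=1e-8)
            assert sol.condensed_fraction_at(math.exp(8.0)) == pytest.approx(
                1.0, abs=1e-8)

    def test_fraction_monotone(self):
        sol = cc.pb_solve(2.0, 10.0)
        x = np.linspace(0.0, 10.0, 200)
        f = sol.condensed_fraction_at(np.exp(x))
        assert np.all(np.diff(f) >= -1e-10)

    def test_manning_limit_at_large_delta(self):
        """Midpoint fraction -> 1 - 1/xi as Delta -> infinity for xi > 1."""
        f40 = cc.pb_solve(2.0, 40.0).midpoint_fraction()
        assert f40 == pytest.approx(0.5, abs=1e-2)
        f15 = cc.pb_solve(1.5, 40.0).midpoint_fraction()
        assert f15 == pytest.approx(1 - 1 / 1.5, abs=2e-2)

    def test_subcritical_fraction_vanishes(self):
        f = cc.pb_solve(0.5, 40.0).midpoint_fraction()
        assert 0.0 <= f < 0.05

    def test_against_independent_bvp_solver(self):
        """Shooting solution vs scipy.solve_bvp on the same boundary-value
        problem (independent algorithm)."""
        from scipy.integrate import solve_bvp

        xi, delta = 2.0, 10.0
        sol = cc.pb_solve(xi, delta)

        def rhs(x, y, p):
            return np.vstack([y[1], -np.exp(np.minimum(p[0] - y[0], 500.0))])

        def bc(ya, yb, p):
            return np.array([ya[0], ya[1] - (2 * xi - 2), yb[1] + 2.0])

        x = np.linspace(0, delta, 200)
        y0 = np.zeros((2, x.size))
        y0[1] = 2 * xi - 2
        res = solve_bvp(rhs, bc, x, y0, p=[0.0], tol=1e-8, max_nodes=40000)
        assert res.success
        xs = np.linspace(0.1, delta - 0.1, 50)
        u_shoot = sol.potential(xs)
        u_bvp = res.sol(xs)[0] + 2 * xs
        assert np.allclose(u_shoot, u_bvp, atol=1e-5)

    def test_profile_neutrality(self):
        """Integral of the PB profile over the cell equals full neutralization."""
        from scipy.integrate import quad
        xi, delta = 2.0, 6.0
        sol = cc.pb_solve(xi, delta)
        # f-integral in x: dN/N = (xi/R^2)*r^2*rho_tilde(x) dx with R=1
        val = quad(lambda x: xi * np.exp(2 * x) * sol.profile(np.exp(x)),
                   0.0, delta, limit=200)[0]
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cc.pb_solve(-1.0, 10.0)
        with pytest.raises(ValueError):
            cc.pb_solve(1.0, 0.0)


class TestOnsetExtrapolation:
    def test_manning_threshold_recovered(self):
        onset = cc.pb_onset_extrapolated((10.0, 20.0, 40.0))
        assert onset == pytest.approx(1.0, abs=0.05)


class TestStrongCoupling:
    def test_two_state_fraction(self):
        assert cc.sc_netz_fraction(0.9) == 0.0
        assert cc.sc_netz_fraction(1.1) == 1.0
        with pytest.raises(ValueError):
            cc.sc_netz_fraction(1.0)

    def test_profile_power_law_and_normalization(self):
        from scipy.integrate import quad
        xi, delta = 2.0, 6.0
        prof = cc.sc_netz_profile(xi, delta)
        # log-log slope is -2 xi everywhere
        s = np.array([1.5, 3.0, 10.0])
        slopes = np.diff(np.log(prof(s))) / np.diff(np.log(s))
        assert np.allclose(slopes, -2 * xi, rtol=1e-10)
        # neutrality over the cell
        val = quad(lambda x: xi * np.exp(2 * x) * prof(np.exp(x)), 0, delta)[0]
        assert val == pytest.approx(1.0, abs=1e-10)
        assert prof(2.0) / prof(1.0) == pytest.approx(2.0 ** (-4), rel=1e-12)


class TestNeedleProfile:
    def test_printed_formula_values(self):
        assert cc.needle_profile(2.0, 1.0) == pytest.approx(0.5, rel=1e-14)
        assert cc.needle_profile(2.0, 2.0) == pytest.approx(0.03125, rel=1e-14)

    def test_evaporation_limit(self):
        assert cc.needle_profile(1.0 + 1e-9, 1.0) == pytest.approx(0.0, abs=1e-15)
        with pytest.raises(ValueError):
            cc.needle_profile(0.9, 1.0)

    def test_integrates_to_manning_fraction(self):
        """2 pi r rho integrated over [R, inf) carries the condensed charge
        fraction 1 - 1/xi."""
        from scipy.integrate import quad
        for xi in (1.5, 2.0, 4.0):
            val = quad(lambda s, xi=xi: xi * s * cc.needle_profile(xi, s),
                       1.0, np.inf)[0]
            assert val == pytest.approx(1 - 1 / xi, rel=1e-8)


class TestOnsetFormulas:
    def test_xi2_of_alpha_values(self):
        assert cc.xi2_of_alpha(1.0) == pytest.approx(2.0)
        assert cc.xi2_of_alpha(0.25) == pytest.approx(5.0)
        assert cc.xi2_of_alpha(math.inf) == 1.0
        assert cc.xi2_of_alpha(0.0) == math.inf
        with pytest.raises(ValueError):
            cc.xi2_of_alpha(-1.0)

    def test_xi2_of_radii_values(self):
        assert cc.xi2_of_radii(0.1, 10.0) == pytest.approx(2.0)
        assert cc.xi2_of_radii(math.exp(-4), math.e) == pytest.approx(1.25)
        with pytest.raises(ValueError):
            cc.xi2_of_radii(2.0, 10.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(alpha=st.floats(0.05, 10.0), ln_D=st.floats(0.1, 60.0))
    def test_schedule_identity(self, alpha, ln_D):
        """xi2_of_radii(D~^-alpha, D~) == 1 + 1/alpha exactly, any D~ > 1
        (alpha*ln D kept inside the double-precision exponential range)."""
        D = math.exp(ln_D)
        assert cc.xi2_of_radii(D ** (-alpha), D) == pytest.approx(
            cc.xi2_of_alpha(alpha), rel=1e-12)

    def test_coupling_at_onset(self):
        assert cc.coupling_at_xi2(5.0, 100.0) == pytest.approx(
            25.0 * math.exp(20.0), rel=1e-12)
        assert cc.coupling_at_xi2(1.0, 50.0) == pytest.approx(math.exp(50.0))
        assert cc.coupling_at_xi2(20.0, 100.0) == pytest.approx(
            400.0 * math.exp(5.0), rel=1e-12)

    def test_radius_schedule(self):
        assert cc.radius_from_alpha(1.0, 100.0) == pytest.approx(-50.0)
        assert cc.radius_from_alpha(0.0, 10.0) == 0.0
        assert cc.radius_from_alpha(math.inf, 10.0) == -10.0

    def test_schedule_coupling_consistency(self):
        """Xi = xi^2 exp(-ln R/a) evaluated at xi = xi2(alpha) reproduces
        coupling_at_xi2 within a factor 2 over alpha in [0.2, 5]."""
        delta = 100.0
        for alpha in (0.2, 0.5, 1.0, 2.0, 5.0):
            xi2 = cc.xi2_of_alpha(alpha)
            Xi_sched = xi2 ** 2 * math.exp(-cc.radius_from_alpha(alpha, delta))
            Xi_form = cc.coupling_at_xi2(xi2, delta)
            assert 0.5 < Xi_sched / Xi_form < 2.0


class TestFreeEnergyArgument:
    def test_lattice_energy_examples(self):
        U_a, _ = cc.lattice_energies(2, 1.0, 1.0)
        assert U_a == pytest.approx(2.0, rel=1e-14)
        # D/H -> 0: the boundary ion sits on the lattice line again
        U_a2, U_b2 = cc.lattice_energies(100, 1.3, 1e-12)
        assert U_b2 == pytest.approx(U_a2, rel=1e-6)

    def test_difference_sum_approaches_log(self):
        """U_a - U_b (image-extended) ~ 2 xi ln(N D/H) at large N D/H, to <1%."""
        N, xi, DH = 1000, 1.0, 10.0
        x = N * DH
        s, lnx = cc.harmonic_sum_approx_check(x)
        assert s == pytest.approx(lnx, rel=0.02)

    def test_asymptotic_root_is_closed_form(self):
        R, D, H, N = math.exp(-50.0), math.exp(50.0), 1000.0, 1000
        root = cc.free_energy_root(N, R, D, H, form="asymptotic")
        assert root == pytest.approx(cc.xi2_of_radii(R * N / H, D * N / H),
                                     rel=1e-12)

    def test_exact_sum_root_near_formula(self):
        """Numerical root of the image-extended difference form within 5% of
        xi2 = 2 for N = 1000, Dtilde = e^50, Rtilde = e^-50."""
        N = 1000
        a = 1.0                      # H/N
        R, D, H = math.exp(-50.0), math.exp(50.0), N * a
        root = cc.free_energy_root(N, R, D, H, form="exact")
        assert root == pytest.approx(2.0, rel=0.05)

    def test_sign_convention(self):
        """Just above the onset the free-energy difference favors the
        completely condensed state (positive dF)."""
        N = 1000
        R, D, H = math.exp(-50.0), math.exp(50.0), float(N)
        xi2 = cc.free_energy_root(N, R, D, H, form="asymptotic")
        above = free_energy_difference(N, xi2 + 0.05, R, D, H)
        below = free_energy_difference(N, xi2 - 0.05, R, D, H)
        assert isinstance(above, FreeEnergyDifference)
        assert above.asymptotic > 0 > below.asymptotic


class TestHarmonicSum:
    def test_asymptotic_offset_is_gamma_minus_ln2(self):
        # the converged sum carries the O(1) offset gamma - ln 2 ~ -0.116
        # in the large-x limit (approached as ~ ln(x)/x)
        s, lnx = cc.harmonic_sum_approx_check(1e6)
        gamma_minus_ln2 = 0.5772156649015329 - math.log(2.0)
        assert s - lnx == pytest.approx(gamma_minus_ln2, abs=1e-4)

    def test_finite_at_x_one(self):
        s, lnx = cc.harmonic_sum_approx_check(1.0)
        assert lnx == 0.0
        assert 0.0 < s < 1.0   # exposes the O(1) error of the estimate

    def test_offset_bounded_over_sweep(self):
        """(sum - ln x) stays bounded by 1 in magnitude over x in [10, 1e6]."""
        for x in (10.0, 100.0, 1e4, 1e6):
            s, lnx = cc.harmonic_sum_approx_check(x)
            assert abs(s - lnx) < 1.0

    def test_partial_sum_mode(self):
        s_partial, _ = cc.harmonic_sum_approx_check(5.0, n_terms=10)
        s_full, _ = cc.harmonic_sum_approx_check(5.0)
        assert s_partial < s_full  # all terms positive
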