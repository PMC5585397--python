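"""Analytic and numerical reference theory for the cylindrical cell model.

Contents:

* the salt-free mean-field (Poisson-Boltzmann) cell model, solved by shooting
  in the logarithmic coordinate x = ln(r/R), which keeps lateral extensions as
  large as Delta = 100 tractable;
* the strong-coupling (two-state) condensed fraction and single-particle
  Boltzmann profile;
* the needle-limit profile rho_tilde(r) = 2 (1 - 1/xi)^2 (R/r)^(2 xi);
* the complete-condensation onset formulas: xi2 = 1 + 1/alpha for the
  radius-shrinking schedule R/a ~ (D/a)^(-alpha), the logarithmic-ratio form
  xi2 = 1 - ln(Dtilde)/ln(Rtilde), the two-configuration free-energy argument
  behind them, and the coupling Xi ~ xi2^2 exp(Delta/xi2) at onset.

Conventions: the reduced mean-field potential u(x) is the potential energy of
a counterion in k_B T (u = 2 xi x near a bare rod); the counterion density is
n(r) = C exp(-u), and Gauss's law gives the cumulative condensed fraction
f(x) = 1 - u'(x)/(2 xi), so f(0) = 0 and f(Delta) = 1 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "PBSolution", "ShrinkSchedule", "pb_solve", "pb_onset_extrapolated",
    "sc_netz_fraction", "sc_netz_profile", "needle_profile",
    "xi2_of_alpha", "xi2_of_radii", "coupling_at_xi2",
    "lattice_energies", "free_energy_difference", "free_energy_root",
    "harmonic_sum_approx_check", "radius_from_alpha", "FreeEnergyDifference",
]


# ---------------------------------------------------------------------------
# Poisson-Boltzmann cell model
# ---------------------------------------------------------------------------

@dataclass
class PBSolution:
    """Mean-field solution of the salt-free cylindrical cell.

    potential(x): reduced potential u at x = ln(r/R) (scalar or array).
    profile(r_over_R): rescaled density rho_tilde.
    condensed_fraction_at(r_over_R): cumulative fraction f = 1 - u'/(2 xi).
    """

    xi: float
    delta: float
    potential: Callable
    _dudx: Callable
    _lnA: float

    def condensed_fraction_at(self, r_over_R) -> float | np.ndarray:
        x = np.log(np.asarray(r_over_R, dtype=float))
        f = 1.0 - self._dudx(x) / (2.0 * self.xi)
        return float(f) if np.ndim(r_over_R) == 0 else f

    def midpoint_fraction(self) -> float:
        """f at the log-midpoint cut ln(r*/R) = Delta/2."""
        return self.condensed_fraction_at(math.exp(self.delta / 2.0))

    def profile(self, r_over_R) -> float | np.ndarray:
        """rho_tilde(r) = A exp(-u) / (2 xi^2), A from the shooting solve."""
        x = np.log(np.asarray(r_over_R, dtype=float))
        rho = math.exp(self._lnA) * np.exp(-self.potential(x)) / (2.0 * self.xi ** 2)
        return float(rho) if np.ndim(r_over_R) == 0 else rho


def _pb_shoot(xi: float, delta: float, lnA: float, rtol: float = 1e-10):
    """Integrate w'' = -exp(lnA - w) with w = u - 2x, w(0)=0, w'(0)=2 xi - 2."""

    def rhs(x, y):
        arg = lnA - y[0]
        return (y[1], -math.exp(arg) if arg < 700.0 else -math.exp(700.0))

    return solve_ivp(rhs, (0.0, delta), [0.0, 2.0 * xi - 2.0],
                     method="RK45", rtol=rtol, atol=1e-12, dense_output=True)


def pb_solve(xi: float, delta: float, rtol: float = 1e-10) -> PBSolution:
    """Solve the salt-free cylindrical-cell PB equation.

    In x = ln(r/R) the equation is u''(x) = -A exp(2x - u) with Gauss-law
    boundary conditions u'(0) = 2 xi (rod charge) and u'(Delta) = 0 (overall
    neutrality).  The normalization constant A > 0 is the single shooting
    parameter, bracketed in ln A and located by Brent's method; u' is
    monotone in A, so the bracket [-800, 20] (A spans e^-800..e^20) is robust
    for xi up to ~100 and Delta up to ~200.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    if delta <= 0:
        raise ValueError("delta must be positive")

    def boundary_residual(lnA):
        s = _pb_shoot(xi, delta, lnA, rtol)
        return s.y[1][-1] + 2.0   # u'(Delta) = w'(Delta) + 2

    lo, hi = -800.0, 20.0
    g_lo, g_hi = boundary_residual(lo), boundary_residual(hi)
    if not (g_lo > 0 > g_hi):
        raise RuntimeError(
            f"PB shooting bracket failed for xi={xi}, delta={delta}: "
            f"residuals ({g_lo:.3g}, {g_hi:.3g})")
    lnA = brentq(boundary_residual, lo, hi, xtol=1e-13, rtol=8.9e-16)
    sol = _pb_shoot(xi, delta, lnA, rtol)

    def potential(x):
        x = np.asarray(x, dtype=float)
        return sol.sol(x)[0] + 2.0 * x

    def dudx(x):
        x = np.asarray(x, dtype=float)
        return sol.sol(x)[1] + 2.0

    return PBSolution(xi=xi, delta=delta, potential=potential, _dudx=dudx,
                      _lnA=lnA)


def pb_onset_extrapolated(deltas=(10.0, 20.0, 40.0),
                          xi_grid=None,
                          window=(0.02, 0.15)) -> float:
    """Manning-onset estimate from PB midpoint fractions at finite Delta.

    For each xi on a grid, f_mid(xi, Delta) is extrapolated to 1/Delta -> 0
    with a polynomial in 1/Delta exactly determined by the supplied sizes;
    the onset is the zero crossing of a straight line fitted to the
    extrapolated order parameter over the small-f window (the standard
    order-parameter-root locator).  With the default sizes {10, 20, 40} this
    reproduces the infinite-dilution threshold xi = 1 to ~1%.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size < 3:
        raise ValueError("need at least 3 lateral extensions")
    if xi_grid is None:
        xi_grid = np.linspace(0.85, 1.45, 25)
    xi_grid = np.asarray(xi_grid, dtype=float)

    F = np.array([[pb_solve(x, d).midpoint_fraction() for d in deltas]
                  for x in xi_grid])
    inv = 1.0 / deltas
    degree = deltas.size - 1
    f_inf = np.array([np.polyval(np.polyfit(inv, F[i], degree), 0.0)
                      for i in range(xi_grid.size)])

    lo, hi = window
    sel = (f_inf >= lo) & (f_inf <= hi)
    if sel.sum() < 2:
        raise RuntimeError("onset window contains fewer than 2 grid points; "
                           "widen xi_grid")
    coef = np.polyfit(xi_grid[sel], f_inf[sel], 1)
    return float(-coef[1] / coef[0])


# ---------------------------------------------------------------------------
# Strong-coupling and needle-limit references
# ---------------------------------------------------------------------------

def sc_netz_fraction(xi: float) -> float:
    """Two-state strong-coupling condensed fraction: 0 below xi = 1, 1 above.

    The transition at xi = 1 is discontinuous; the value exactly at the
    critical point is undefined.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    if xi == 1.0:
        raise ValueError("sc fraction undefined exactly at xi = 1")
    return 0.0 if xi < 1.0 else 1.0


def sc_netz_profile(xi: float, delta: float) -> Callable:
    """Single-particle Boltzmann profile in the bare-rod potential.

    rho_tilde(r) = A (R/r)^(2 xi) with A fixed by cell neutrality
    (the integral of 2 pi r rho over [R, D] equals the line density).
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    if xi == 1.0:
        A = 1.0 / delta
    else:
        A = (2.0 * xi - 2.0) / (xi * (1.0 - math.exp(-(2.0 * xi - 2.0) * delta)))

    def profile(r_over_R):
        s = np.asarray(r_over_R, dtype=float)
        out = A * s ** (-2.0 * xi)
        return float(out) if np.ndim(r_over_R) == 0 else out

    return profile


def needle_profile(xi: float, r_over_R) -> float | np.ndarray:
    """Needle-limit profile rho_tilde(r) = 2 (1 - 1/xi)^2 (R/r)^(2 xi).

    Valid for xi > 1 (below, the prefactor loses meaning: complete
    evaporation).  Integrates over [R, inf) to the Manning fraction 1 - 1/xi
    of neutralization.
    """
    if xi <= 1.0:
        raise ValueError("needle profile requires xi > 1 (evaporation regime)")
    s = np.asarray(r_over_R, dtype=float)
    if np.any(s < 1.0):
        raise ValueError("r_over_R must be >= 1")
    out = 2.0 * (1.0 - 1.0 / xi) ** 2 * s ** (-2.0 * xi)
    return float(out) if np.ndim(r_over_R) == 0 else out


# ---------------------------------------------------------------------------
# Complete-condensation onset formulas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShrinkSchedule:
    """Radius-shrinking schedule Rtilde = c * Dtilde^(-alpha).

    alpha = 0 keeps R fixed while D grows; alpha = inf is the line-charge
    limit R -> 0 at fixed D (both limits are taken explicitly by the
    formulas).
    """

    alpha: float
    c: float = 1.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.c <= 0:
            raise ValueError("c must be positive")

    def ln_R(self, delta: float) -> float:
        return radius_from_alpha(self.alpha, delta) + math.log(self.c)

    def ln_D(self, delta: float) -> float:
        return self.ln_R(delta) + delta

    def xi2(self) -> float:
        return xi2_of_alpha(self.alpha)


def radius_from_alpha(alpha: float, delta: float) -> float:
    """ln(R/a) = -alpha*Delta/(alpha+1), so that ln(D/a) = Delta/(alpha+1)."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if math.isinf(alpha):
        return -delta
    return -alpha * delta / (alpha + 1.0)


def xi2_of_alpha(alpha: float) -> float:
    """Complete-condensation onset xi2 = 1 + 1/alpha.

    alpha -> 0 gives xi2 -> inf (mean-field behavior, no second transition at
    finite xi); alpha = inf gives xi2 = 1 (merges with the Manning point:
    the strong-coupling discontinuity).
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if alpha == 0:
        return math.inf
    if math.isinf(alpha):
        return 1.0
    return 1.0 + 1.0 / alpha


def xi2_of_radii(R_tilde: float, D_tilde: float) -> float:
    """Onset from the logarithmic radii: xi2 = 1 - ln(Dtilde)/ln(Rtilde).

    Requires Rtilde < 1 (R << q/tau) and Dtilde > 1, under which xi2 >= 1.
    """
    if not (0 < R_tilde < 1):
        raise ValueError("need 0 < R_tilde < 1 (R much smaller than q/tau)")
    if D_tilde <= 1:
        raise ValueError("need D_tilde > 1")
    return 1.0 - math.log(D_tilde) / math.log(R_tilde)


def coupling_at_xi2(xi2: float, delta: float) -> float:
    """Coupling parameter at the onset: Xi ~ xi2^2 exp(Delta/xi2)."""
    if xi2 < 1:
        raise ValueError("xi2 must be >= 1")
    if delta <= 0:
        raise ValueError("delta must be positive")
    return xi2 ** 2 * math.exp(delta / xi2)


def lattice_energies(N: int, xi: float, D_over_H: float
                     ) -> tuple[float, float]:
    """Coulomb energies of the two test configurations (within one period).

    (a): all N ions equally spaced on the rod (zeta_l = l/N, rho ~ 0):
         U_a = 2 (xi/N) sum_{l=1}^{N-1} N/l;
    (b): one ion moved to the outer boundary r = D:
         U_b = 2 (xi/N) sum_{l=1}^{N-1} 1/sqrt((D/H)^2 + (l/N)^2).

    The sums run over the N-1 partners inside one period; the periodic-image
    extension (which each sum needs individually to converge) is applied to
    the *difference* in `free_energy_difference`.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    l = np.arange(1, N, dtype=float)
    U_a = 2.0 * xi / N * float(np.sum(N / l))
    U_b = 2.0 * xi / N * float(np.sum(1.0 / np.sqrt(D_over_H ** 2 + (l / N) ** 2)))
    return U_a, U_b


def harmonic_sum_approx_check(x: float, n_terms: int | None = None
                              ) -> tuple[float, float]:
    """Evaluate S(x) = sum_{l>=1} (1/l - 1/sqrt(x^2 + l^2)) next to ln x.

    Returns (sum, ln x).  Without n_terms the sum is converged using the
    analytic Euler-Maclaurin tail.  Note the converged sum approaches
    ln x + gamma - ln 2 (an O(1) offset ~= -0.116): the logarithmic estimate
    is a leading-order approximation, excellent when ln x is large.
    """
    if x <= 0:
        raise ValueError("x must be positive")
    if n_terms is not None:
        l = np.arange(1, n_terms + 1, dtype=float)
        return float(np.sum(1.0 / l - 1.0 / np.sqrt(x * x + l * l))), math.log(x)

    L = int(min(2_000_000, max(10_000, 20.0 * x)))
    l = np.arange(1, L + 1, dtype=float)
    s = float(np.sum(1.0 / l - 1.0 / np.sqrt(x * x + l * l)))
    a = L + 1.0
    integral = math.log(x / 2.0) - math.log(a) + math.asinh(a / x)
    h0 = 1.0 / a - 1.0 / math.hypot(x, a)
    h1 = -1.0 / a ** 2 + a / math.hypot(x, a) ** 3
    s += integral + h0 / 2.0 - h1 / 12.0
    return s, math.log(x)


@dataclass(frozen=True)
class FreeEnergyDifference:
    """dF = F(one ion at the boundary) - F(complete condensation).

    Positive dF favors the completely condensed state.
    """

    exact: float        # image-extended difference sum
    asymptotic: float   # 2 (xi-1) ln(D/R) - 2 xi ln(D/a)
    regime_ok: bool     # R << H/N and D >> H/N as the derivation assumes


def free_energy_difference(N: int, xi: float, R: float, D: float, H: float
                           ) -> FreeEnergyDifference:
    """Two-configuration free-energy difference behind the xi2 formulas.

    exact: dF = 2 (xi - 1) ln(D/R) - [U_a - U_b] with the (a)-(b) energy
    difference extended over all periodic images, i.e.
    U_a - U_b = 2 xi S(N D / H) with S the convergent harmonic-minus-image
    sum; asymptotic replaces S by ln(N D / H) = ln(D/a).  The root of either
    form in xi reproduces xi2 = 1 - ln(Dtilde)/ln(Rtilde) up to the O(1)
    accuracy of the logarithmic estimate.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    a_unit = H / N                      # longitudinal spacing = q/tau
    regime_ok = (R < 0.5 * a_unit) and (D > 2.0 * a_unit)
    ln_DR = math.log(D / R)
    x = N * D / H                       # = D/a
    s_conv, _ = harmonic_sum_approx_check(x)
    exact = 2.0 * (xi - 1.0) * ln_DR - 2.0 * xi * s_conv
    asym = 2.0 * (xi - 1.0) * ln_DR - 2.0 * xi * math.log(x)
    return FreeEnergyDifference(exact=exact, asymptotic=asym,
                                regime_ok=regime_ok)


def free_energy_root(N: int, R: float, D: float, H: float,
                     form: str = "exact") -> float:
    """Onset xi2 as the root in xi of the chosen free-energy form.

    Both forms are affine in xi, so the root is closed-form.
    """
    ln_DR = math.log(D / R)
    x = N * D / H
    if form == "exact":
        s, _ = harmonic_sum_approx_check(x)
    elif form == "asymptotic":
        s = math.log(x)
    else:
        raise ValueError("form must be 'exact' or 'asymptotic'")
    denom = ln_DR - s
    if denom <= 0:
        raise ValueError("no onset in the physical regime (ln(D/R) <= S)")
    return ln_DR / denom
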