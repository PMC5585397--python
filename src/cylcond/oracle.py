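"""Independent brute-force oracles and deterministic synthetic fixtures.

Central subtlety: the 1D image sum of 1/r is conditionally divergent (it
diverges logarithmically with the image cutoff together with the neutralizing
background), so only *differences* of the periodic pair potential between two
separations are physical.  The oracle therefore computes difference sums

    sum_{n=-M}^{M} [ 1/d(p1, n) - 1/d(p0, n) ],   d(p, n) = sqrt(rho^2 + (zeta + n H)^2),

whose symmetric truncation converges as O(1/M^2) and is accelerated by
Richardson extrapolation.  Everything the resummed evaluators claim is checked
against these differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .model import CellModel, IonConfiguration
from .scaling import ScalingDataset

__all__ = ["OracleGrid", "BruteForceDiff", "brute_force_periodic_sum_diff",
           "synthetic_collapse_data", "fixture_configurations", "default_grid"]


class BruteForceDiff(NamedTuple):
    value: float
    error_estimate: float


@dataclass(frozen=True)
class OracleGrid:
    """Evaluation triples (rho, zeta, H) plus a reference triple.

    Potentials are compared as differences against the reference point, the
    only well-defined comparison for a conditionally divergent image sum.
    """

    points: np.ndarray            # (n, 2): rho, zeta
    reference: tuple[float, float]
    H: float = 1.0

    def __post_init__(self):
        pts = np.vstack([self.points, np.asarray(self.reference)[None, :]])
        zmod = np.abs(pts[:, 1] / self.H - np.round(pts[:, 1] / self.H))
        if np.any((pts[:, 0] == 0) & (zmod == 0)):
            raise ValueError("grid contains an image-plane singularity")


def default_grid(n: int = 100, H: float = 1.0, seed: int = 12345) -> OracleGrid:
    """Deterministic quasi-random grid spanning near-axis to far-field."""
    rng = np.random.Generator(np.random.Philox(seed))
    log_rho = rng.uniform(math.log(1e-4), math.log(5.0), n)
    rho = H * np.exp(log_rho)
    zeta = H * rng.uniform(-1.5, 1.5, n)
    return OracleGrid(points=np.column_stack([rho, zeta]),
                      reference=(0.25 * H, 0.1 * H), H=H)


def _truncated_diff(p1, p0, H: float, M: int) -> float:
    n = np.arange(-M, M + 1, dtype=float)
    d1 = np.sqrt(p1[0] ** 2 + (p1[1] + n * H) ** 2)
    d0 = np.sqrt(p0[0] ** 2 + (p0[1] + n * H) ** 2)
    if np.any(d1 == 0) or np.any(d0 == 0):
        raise ZeroDivisionError("singular distance in image sum")
    return float(np.sum(1.0 / d1 - 1.0 / d0))


def brute_force_periodic_sum_diff(p1, p0, H: float = 1.0, M: int = 4096
                                  ) -> BruteForceDiff:
    """Difference of image-summed potentials v(p1) - v(p0) by direct summation.

    Sums n = -M..M at three cutoffs (M/4, M/2, M) and removes the O(1/M^2)
    and O(1/M^4) tails by two Richardson steps.  The returned error estimate
    is the magnitude of the last Richardson correction, a bound that the
    convergence property test validates against an actual cutoff doubling.
    """
    if M < 4:
        raise ValueError("M must be at least 4")
    s1 = _truncated_diff(p1, p0, H, M // 4)
    s2 = _truncated_diff(p1, p0, H, M // 2)
    s3 = _truncated_diff(p1, p0, H, M)
    r1 = s2 + (s2 - s1) / 3.0          # kill O(1/M^2)
    r2 = s3 + (s3 - s2) / 3.0
    value = r2 + (r2 - r1) / 15.0      # kill O(1/M^4)
    return BruteForceDiff(value=value, error_estimate=abs(r2 - r1) + 1e-15)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def _logistic(s):
    return 1.0 / (1.0 + np.exp(-s))


def synthetic_collapse_data(beta: float, nu: float, xi_c: float,
                            deltas, xi_grid=None, noise_sd: float = 0.03,
                            seed: int = 0, zeta_grid=None,
                            coincident: bool = False) -> ScalingDataset:
    """Synthetic order-parameter data with known exponents.

    m = clip(Delta^(-beta/nu) g(Delta^(1/nu) zeta) (1 + eps), 0, 1) with
    logistic scaling function g and eps ~ N(0, noise_sd^2); deterministic per
    seed.  Either an explicit xi_grid (shared across sizes) or, with
    `coincident=True`, per-size xi grids chosen so the scaling variable
    u = Delta^(1/nu) zeta takes identical values for every size (useful for
    exact-collapse tests).
    """
    if beta <= 0 or nu <= 0:
        raise ValueError("beta and nu must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    deltas = np.asarray(deltas, dtype=float)
    rng = np.random.Generator(np.random.Philox(seed))

    rows_d, rows_xi, rows_m, rows_e = [], [], [], []
    if coincident:
        if zeta_grid is None:
            u_grid = np.linspace(-1.5, 1.5, 13)
        else:
            u_grid = np.asarray(zeta_grid, dtype=float)
        for d in deltas:
            zeta = u_grid * d ** (-1.0 / nu)
            xi = xi_c / (1.0 - zeta)
            rows_d.append(np.full(xi.size, d))
            rows_xi.append(xi)
    else:
        if xi_grid is None:
            zg = np.linspace(-0.12, 0.12, 17)
            xi_grid = xi_c / (1.0 - zg)
        xi_grid = np.asarray(xi_grid, dtype=float)
        for d in deltas:
            rows_d.append(np.full(xi_grid.size, d))
            rows_xi.append(xi_grid)

    for d_arr, xi_arr in zip(rows_d, rows_xi):
        zeta = 1.0 - xi_c / xi_arr
        amp = d_arr ** (-beta / nu)
        m_model = amp * _logistic(d_arr ** (1.0 / nu) * zeta)
        eps = noise_sd * rng.standard_normal(xi_arr.size)
        m = np.clip(m_model * (1.0 + eps), 0.0, 1.0)
        # nominal error floor for noiseless fixtures (m_err must be positive)
        m_err = np.maximum(noise_sd, 1e-4) * m_model
        rows_m.append(m)
        rows_e.append(m_err)

    return ScalingDataset(
        delta=np.concatenate(rows_d),
        xi=np.concatenate(rows_xi),
        k=np.ones(sum(a.size for a in rows_d), dtype=int),
        m=np.concatenate(rows_m),
        m_err=np.concatenate(rows_e),
        xi_c=xi_c,
    )


def fixture_configurations(xi: float = 1.0):
    """Deterministic tiny configurations with hand-checkable energies.

    Returns {name: (CellModel, IonConfiguration)}:
    * single_at_R  — one ion on the rod surface: beta*H = 0;
    * single_at_eR — one ion at r = e*R: beta*H = 2*xi;
    * pair_antipodal — two ions at r = R, theta 0 and pi, z 0 and H/2
      (H = 2), energy checkable against the brute-force oracle;
    * ring_of_5 — five ions equally spaced in theta and z at r = 2R.
    """
    out = {}
    m1 = CellModel(N=1, xi=xi, R=1.0, D=math.e ** 3)
    out["single_at_R"] = (m1, IonConfiguration(
        np.array([1.0]), np.array([0.0]), np.array([0.0])))
    out["single_at_eR"] = (m1, IonConfiguration(
        np.array([math.e]), np.array([0.0]), np.array([0.0])))
    m2 = CellModel(N=2, xi=xi, R=1.0, D=math.e ** 2)
    out["pair_antipodal"] = (m2, IonConfiguration(
        np.array([1.0, 1.0]), np.array([0.0, math.pi]), np.array([0.0, 1.0])))
    m5 = CellModel(N=5, xi=xi, R=1.0, D=math.e ** 2)
    th = 2.0 * np.pi * np.arange(5) / 5.0
    out["ring_of_5"] = (m5, IonConfiguration(
        np.full(5, 2.0), th, np.arange(5, dtype=float)))
    return out
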