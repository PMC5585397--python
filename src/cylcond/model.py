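"""Reduced-unit cell model and energy evaluation.

Geometry: an infinite charged cylinder of radius R on the axis of a concentric
outer cylinder of radius D; N pointlike counterions of valency q live in the
annulus.  Reduced units used throughout the package:

* lengths in a = q/tau, the longitudinal spacing of counterions when they
  neutralize the rod as a 1D lattice; charge neutrality then fixes the
  periodic box height to H = N;
* energies in k_B T.

With these units l_B q^2 = xi * a, so the reduced Hamiltonian is

    beta H = xi * sum_{i<j} v(rho_ij, zeta_ij; H) + 2 xi * sum_i ln(r_i / R),

where v is the 1D-periodic Coulomb factor (see `cylcond.pairpot`) and the
one-body logarithm is the bare-rod attraction (the rod's own periodic images
are implied by the logarithm; no Lekner sum is needed for it).  The
position-independent interaction of an ion with its own periodic replicas is
dropped: it cancels in every energy difference and in the energy variance.

The couplings: Manning parameter xi = q l_B tau, coupling parameter
Xi = 2 pi q^3 l_B^2 sigma = xi^2 * (a/R), Gouy-Chapman length mu = R/xi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import one_ion_pair_sum, total_energy_kernel
from .pairpot import LeknerParams

__all__ = ["CellModel", "IonConfiguration", "total_energy", "energy_delta"]


@dataclass(frozen=True)
class CellModel:
    """Geometry and couplings of the cylindrical cell in reduced units."""

    N: int
    xi: float
    R: float
    D: float

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        if self.xi <= 0:
            raise ValueError("xi must be positive")
        if not (0 < self.R < self.D):
            raise ValueError("need 0 < R < D")

    @property
    def delta(self) -> float:
        """Lateral extension Delta = ln(D/R)."""
        return math.log(self.D / self.R)

    @property
    def H(self) -> float:
        """Periodic box height; charge neutrality fixes H = N (units of a)."""
        return float(self.N)

    @property
    def Xi(self) -> float:
        """Coupling parameter Xi = xi^2 * (a/R) = xi^2 / R (R in units of a)."""
        return self.xi ** 2 / self.R

    @property
    def mu(self) -> float:
        """Gouy-Chapman length mu = R / xi (units of a)."""
        return self.R / self.xi

    @property
    def r_star(self) -> float:
        """Condensation cut radius, ln(r*/R) = Delta/2, i.e. r* = sqrt(R D)."""
        return math.sqrt(self.R * self.D)

    @classmethod
    def from_alpha(cls, N: int, xi: float, alpha: float, delta: float,
                   c: float = 1.0) -> "CellModel":
        """Build the cell from the radius-shrinking schedule R/a ~ (D/a)^-alpha.

        ln(R/a) = -alpha*Delta/(alpha+1) + ln c and ln(D/R) = Delta, so that
        D -> infinity and R -> 0 are approached at relative rate alpha.
        """
        from .theory import radius_from_alpha

        ln_R = radius_from_alpha(alpha, delta) + math.log(c)
        return cls(N=N, xi=xi, R=math.exp(ln_R), D=math.exp(ln_R + delta))

    @classmethod
    def from_coupling(cls, N: int, xi: float, Xi: float, delta: float) -> "CellModel":
        """Build the cell from (xi, Xi, Delta); R = xi^2 / Xi in units of a."""
        R = xi ** 2 / Xi
        return cls(N=N, xi=xi, R=R, D=R * math.exp(delta))


@dataclass
class IonConfiguration:
    """Positions of N counterions with a cached total reduced energy.

    r in [R, D] (units of a), theta in [0, 2*pi), z in [0, H) periodic.
    """

    r: np.ndarray
    theta: np.ndarray
    z: np.ndarray
    energy: float | None = field(default=None)

    def __post_init__(self):
        self.r = np.ascontiguousarray(self.r, dtype=float)
        self.theta = np.ascontiguousarray(self.theta, dtype=float)
        self.z = np.ascontiguousarray(self.z, dtype=float)
        if not (self.r.shape == self.theta.shape == self.z.shape):
            raise ValueError("r, theta, z must have identical shapes")

    @property
    def N(self) -> int:
        return self.r.shape[0]

    def validate(self, model: CellModel) -> None:
        if self.N != model.N:
            raise ValueError("configuration size does not match model.N")
        if np.any(self.r < model.R) or np.any(self.r > model.D):
            raise ValueError("all radii must lie in [R, D]")
        if np.any(self.z < 0) or np.any(self.z >= model.H):
            raise ValueError("all z must lie in [0, H)")

    def copy(self) -> "IonConfiguration":
        return IonConfiguration(self.r.copy(), self.theta.copy(), self.z.copy(),
                                self.energy)


def total_energy(config: IonConfiguration, model: CellModel,
                 params: LeknerParams | None = None) -> float:
    """Total reduced energy beta*H of a configuration (units of k_B T).

    Excludes the configuration-independent self-image constant.  `params` is
    accepted for interface symmetry; the uniform near-axis evaluator meets any
    tolerance the series would (both are cross-validated against the
    brute-force oracle).
    """
    config.validate(model)
    if config.N >= 2:
        d2 = _min_pair_separation_sq(config, model.H)
        if d2 == 0.0:
            raise ValueError("ion overlap: coincident positions")
    return total_energy_kernel(config.r, config.theta, config.z,
                               model.xi, model.R, model.H)


def _min_pair_separation_sq(config: IonConfiguration, H: float) -> float:
    r, th, z = config.r, config.theta, config.z
    x = r * np.cos(th)
    y = r * np.sin(th)
    dz = z[:, None] - z[None, :]
    dz -= np.round(dz / H) * H
    d2 = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2 + dz ** 2
    iu = np.triu_indices(config.N, k=1)
    return float(np.min(d2[iu]))


def energy_delta(config: IonConfiguration, i: int, new_position, model: CellModel,
                 params: LeknerParams | None = None) -> float:
    """beta*H(new) - beta*H(old) for moving ion i to (r', theta', z').

    Computed from the 2(N-1) affected pair terms plus the one changed one-body
    log term.
    """
    if not (0 <= i < config.N):
        raise IndexError("ion index out of range")
    rp, thp, zp = map(float, new_position)
    if not (model.R <= rp <= model.D):
        raise ValueError("new radius outside [R, D]")
    if not (0.0 <= zp < model.H):
        raise ValueError("new z outside [0, H)")
    old = one_ion_pair_sum(config.r, config.theta, config.z, i,
                           config.r[i], config.theta[i], config.z[i], model.H)
    new = one_ion_pair_sum(config.r, config.theta, config.z, i, rp, thp, zp,
                           model.H)
    return model.xi * (new - old) + 2.0 * model.xi * math.log(rp / config.r[i])


def apply_move(config: IonConfiguration, i: int, new_position, model: CellModel
               ) -> IonConfiguration:
    """Return a copy with ion i moved and the cached energy updated by delta."""
    de = energy_delta(config, i, new_position, model)
    out = config.copy()
    out.r[i], out.theta[i], out.z[i] = map(float, new_position)
    if config.energy is not None:
        out.energy = config.energy + de
    return out
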