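"""1D-periodic Coulomb pair potential (Lekner / Sperb summation).

A point charge interacting with another charge and all of its periodic images
along the cylinder axis (period H) has the conditionally convergent sum
``sum_n 1/sqrt(rho^2 + (zeta + n H)^2)``.  Resummation gives the rapidly
convergent Bessel form

    v(rho, zeta) = (2/H) [ 2 sum_{n>=1} K0(2 pi n rho / H) cos(2 pi n zeta / H)
                           - ln(rho / H) ] + C0/H,

with the additive constant fixed by the convention C0 = 0; only energy
*differences* enter Metropolis sampling and the heat capacity, so C0 is
physically irrelevant, but both evaluators here share the same constant so
they can be mixed freely.

Two evaluation schemes are provided:

* the Bessel (Fourier) series, truncated adaptively — efficient for
  rho/H >~ a few percent, increasingly slow as rho -> 0;
* a Sperb-style near-axis scheme (`pair_potential`): the nearest images are
  summed directly and the remainder by Euler-Maclaurin with the exact tail
  integral.  This form is uniformly accurate at *all* separations and is what
  the Monte Carlo kernels use.

`periodic_pair_potential` switches between the two according to
``LeknerParams.rho_switch``, as the classic implementations do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import k0

from ._kernels import pair_potential_unit

__all__ = ["LeknerParams", "pair_potential", "periodic_pair_potential",
           "pair_potential_series", "tabulate_pair_potential"]


@dataclass(frozen=True)
class LeknerParams:
    """Truncation/switch parameters of the periodic pair-potential evaluation.

    n_fourier : maximum number of K0-series terms retained (the series is cut
        earlier as soon as K0(2 pi n rho/H) < tol).
    rho_switch : transverse separations below rho_switch*H use the near-axis
        (Sperb-style) evaluation instead of the series.
    tol : target absolute accuracy of the pair potential.
    """

    n_fourier: int = 100_000
    rho_switch: float = 0.05
    tol: float = 1e-10

    def __post_init__(self):
        if self.n_fourier < 1:
            raise ValueError("n_fourier must be a positive integer")
        if self.rho_switch <= 0:
            raise ValueError("rho_switch must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def pair_potential(rho, zeta, H=1.0):
    """Near-axis (Sperb-style) evaluation of v(rho, zeta; H), any separation.

    Vectorized over rho/zeta.  Raises for an exact self-overlap
    (rho = 0 and zeta = 0 mod H).
    """
    rho = np.asarray(rho, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be nonnegative")
    scalar = rho.ndim == 0 and zeta.ndim == 0
    rho_u, zeta_u = np.broadcast_arrays(rho / H, zeta / H)
    out = np.empty(rho_u.shape)
    it = np.nditer(rho_u, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        p = float(rho_u[idx])
        zz = float(zeta_u[idx])
        zw = zz - round(zz)
        if p == 0.0 and zw == 0.0:
            raise ValueError("self-overlap: rho = 0 with zeta on an image plane")
        out[idx] = pair_potential_unit(p, zz) / H
    return float(out) if scalar else out


def pair_potential_series(rho, zeta, H=1.0, params: LeknerParams | None = None):
    """Bessel-series evaluation of v(rho, zeta; H) (scalar), C0 = 0.

    Terms are added until K0(2 pi n rho/H) < params.tol, capped at
    params.n_fourier.
    """
    params = params or LeknerParams()
    p = float(rho) / H
    zz = float(zeta) / H
    if p <= 0.0:
        raise ValueError("the series form requires rho > 0")
    s = 0.0
    block = 64
    n = 1
    while n <= params.n_fourier:
        ns = np.arange(n, min(n + block, params.n_fourier + 1))
        terms = k0(2.0 * np.pi * ns * p)
        s += float(np.sum(terms * np.cos(2.0 * np.pi * ns * zz)))
        if terms[-1] < params.tol * 0.01 or ns[-1] == params.n_fourier:
            break
        n += block
    return 2.0 * (2.0 * s - np.log(p)) / H


def periodic_pair_potential(rho, zeta, H=1.0, params: LeknerParams | None = None):
    """v(rho, zeta; H): series for rho >= rho_switch*H, near-axis scheme below.

    This is the image-summed 1/r interaction of two unit charges in a box of
    height H with 1D periodic boundary conditions, up to the additive
    convention C0 = 0.  Even and H-periodic in zeta.
    """
    params = params or LeknerParams()
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    zeta_arr = np.atleast_1d(np.asarray(zeta, dtype=float))
    rho_b, zeta_b = np.broadcast_arrays(rho_arr, zeta_arr)
    out = np.empty(rho_b.shape)
    flat_r = rho_b.ravel()
    flat_z = zeta_b.ravel()
    flat_o = out.ravel()
    for i in range(flat_r.size):
        p = flat_r[i]
        if p < 0:
            raise ValueError("rho must be nonnegative")
        zw = (p / H, (flat_z[i] / H) - round(flat_z[i] / H))
        if zw[0] == 0.0 and zw[1] == 0.0:
            raise ValueError("self-overlap: rho = 0 with zeta on an image plane")
        if p >= params.rho_switch * H:
            flat_o[i] = pair_potential_series(p, flat_z[i], H, params)
        else:
            flat_o[i] = pair_potential_unit(p / H, flat_z[i] / H) / H
    if np.ndim(rho) == 0 and np.ndim(zeta) == 0:
        return float(out.ravel()[0])
    return out


def tabulate_pair_potential(rhos, zetas, H=1.0, params: LeknerParams | None = None):
    """Tabulate v on a (rho, zeta) grid; returns an array of rows (rho, zeta, v).

    Intended for debugging/CSV export.
    """
    rows = []
    for p in np.asarray(rhos, dtype=float):
        for zz in np.asarray(zetas, dtype=float):
            rows.append((p, zz, periodic_pair_potential(p, zz, H, params)))
    return np.array(rows)
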