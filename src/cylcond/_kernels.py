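"""Numba-compiled kernels for the Monte Carlo engine.

All lengths are in units of the longitudinal ion spacing a = q/tau and all
energies in units of k_B T.  The periodic Coulomb pair interaction is evaluated
by a Sperb-style direct image sum with an analytic Euler-Maclaurin tail, which
is uniformly accurate (~1e-13) at all transverse separations and cheap enough
for the inner MC loop.  Its additive constant matches the C0 = 0 convention of
the Bessel-series (Lekner) form, i.e. the two evaluators agree pointwise, not
just in differences.
"""

import math

import numpy as np
from numba import njit

TWO_GAMMA_MINUS_2LN2 = 2.0 * 0.5772156649015328606 - 2.0 * 0.6931471805599453094


@njit(cache=True)
def pair_potential_unit(rho, zeta):
    """Dimensionless 1D-periodic Coulomb factor v(rho, zeta) for unit period.

    Equals 2*[2*sum_n K0(2*pi*n*rho)*cos(2*pi*n*zeta) - ln rho] (the Lekner
    series with C0 = 0), evaluated as a direct image sum over |n| <= N0 with
    the remainder summed by Euler-Maclaurin using the exact antiderivative.
    Valid for any rho >= 0 except the self-overlap rho = 0, zeta = 0 (mod 1),
    where it diverges (returns +inf).
    """
    z = zeta - round(zeta)  # wrap to [-0.5, 0.5]; v is even and periodic
    if rho >= 2.0:
        # far field: the Bessel series needs only a couple of terms, each
        # evaluated by the large-argument asymptotic expansion of K0
        # (x >= 4*pi here, expansion accurate to ~1e-13)
        s = 0.0
        n = 1
        while True:
            x = 2.0 * math.pi * n * rho
            if x > 35.0:   # exp(-35) below double precision of the result
                break
            ix = 1.0 / (8.0 * x)
            k0x = (math.sqrt(0.5 * math.pi / x) * math.exp(-x)
                   * (1.0 + ix * (-1.0 + ix * (4.5 + ix * (-37.5 + ix * 459.375)))))
            s += k0x * math.cos(2.0 * math.pi * n * z)
            n += 1
        return 2.0 * (2.0 * s - math.log(rho))
    r2 = rho * rho
    n0 = 24  # explicit images; EM tail handles the remainder
    F = 1.0 / math.sqrt(r2 + z * z)
    for n in range(1, n0 + 1):
        F += (1.0 / math.sqrt(r2 + (n + z) * (n + z))
              + 1.0 / math.sqrt(r2 + (n - z) * (n - z))
              - 2.0 / n)
    a = float(n0 + 1)
    up = a + z
    um = a - z
    r2p = r2 + up * up
    r2m = r2 + um * um
    sqp = math.sqrt(r2p)
    sqm = math.sqrt(r2m)
    # exact tail integral: int_a^inf [1/sqrt(r2+(x+z)^2) + 1/sqrt(r2+(x-z)^2) - 2/x] dx
    integral = math.log(4.0 * a * a / ((up + sqp) * (um + sqm)))
    # Euler-Maclaurin corrections with analytic derivatives of the summand
    h0 = 1.0 / sqp + 1.0 / sqm - 2.0 / a
    h1 = -up / (r2p * sqp) - um / (r2m * sqm) + 2.0 / (a * a)
    h3 = (3.0 * up * (3.0 * r2 - 2.0 * up * up) / (r2p * r2p * r2p * sqp)
          + 3.0 * um * (3.0 * r2 - 2.0 * um * um) / (r2m * r2m * r2m * sqm)
          + 12.0 / (a * a * a * a))
    h5 = (-15.0 * up * (63.0 * up**4 - 70.0 * up * up * r2p + 15.0 * r2p * r2p)
          / (r2p**5 * sqp)
          - 15.0 * um * (63.0 * um**4 - 70.0 * um * um * r2m + 15.0 * r2m * r2m)
          / (r2m**5 * sqm)
          + 240.0 / a**6)
    tail = integral + 0.5 * h0 - h1 / 12.0 + h3 / 720.0 - h5 / 30240.0
    return F + tail + TWO_GAMMA_MINUS_2LN2


@njit(cache=True)
def _pair_v(ri, thi, zi, rj, thj, zj, H):
    """Periodic pair interaction v(rho_ij, zeta_ij; H) between two ions."""
    rho = math.sqrt(max(ri * ri + rj * rj - 2.0 * ri * rj * math.cos(thi - thj), 0.0))
    dz = (zi - zj) / H
    return pair_potential_unit(rho / H, dz) / H


@njit(cache=True)
def total_pair_sum(r, th, z, H):
    """Sum of v over all pairs i < j."""
    N = r.shape[0]
    s = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            s += _pair_v(r[i], th[i], z[i], r[j], th[j], z[j], H)
    return s


@njit(cache=True)
def one_ion_pair_sum(r, th, z, i, ri, thi, zi, H):
    """Sum of v between a (possibly displaced) ion i and all other ions."""
    N = r.shape[0]
    s = 0.0
    for j in range(N):
        if j != i:
            s += _pair_v(ri, thi, zi, r[j], th[j], z[j], H)
    return s


@njit(cache=True)
def two_ion_pair_sum(r, th, z, ia, ib, ra, rb, H):
    """Pair sum touching ions ia, ib at trial radii ra, rb (angles/z kept)."""
    N = r.shape[0]
    s = 0.0
    for j in range(N):
        if j != ia and j != ib:
            s += _pair_v(ra, th[ia], z[ia], r[j], th[j], z[j], H)
            s += _pair_v(rb, th[ib], z[ib], r[j], th[j], z[j], H)
    s += _pair_v(ra, th[ia], z[ia], rb, th[ib], z[ib], H)
    return s


@njit(cache=True)
def total_energy_kernel(r, th, z, xi, R, H):
    """Total reduced energy beta*H (self-image constant dropped)."""
    e = xi * total_pair_sum(r, th, z, H)
    for i in range(r.shape[0]):
        e += 2.0 * xi * math.log(r[i] / R)
    return e


@njit(cache=True)
def propose_local_kernel(rng, ri, thi, zi, step, R, D, H):
    """Uniform displacement in a Cartesian cube of half-width `step`.

    Returns (ok, r', th', z'); ok = False when the trial radius leaves [R, D]
    (counted as an attempted-and-rejected move by the caller).
    """
    x = ri * math.cos(thi) + step * (2.0 * rng.random() - 1.0)
    y = ri * math.sin(thi) + step * (2.0 * rng.random() - 1.0)
    zp = (zi + step * (2.0 * rng.random() - 1.0)) % H
    rp = math.sqrt(x * x + y * y)
    if rp < R or rp > D:
        return False, ri, thi, zi
    return True, rp, math.atan2(y, x) % (2.0 * math.pi), zp


@njit(cache=True)
def propose_centrifugal_kernel(rng, R, delta, H):
    """Log-uniform radial resampling: r' = R*exp(u*Delta), fresh theta and z."""
    rp = R * math.exp(rng.random() * delta)
    thp = 2.0 * math.pi * rng.random()
    zp = H * rng.random()
    return rp, thp, zp


@njit(cache=True)
def _metropolis_accept(rng, ln_acc):
    if ln_acc >= 0.0:
        return True
    if ln_acc < -700.0:
        return False
    return rng.random() < math.exp(ln_acc)


@njit(cache=True)
def collapse_objective_kernel(u, w, s2, k_id, d_id, n_k, n_d, snap_tol):
    """Interpolation-residual collapse objective (see cylcond.scaling).

    For every point, linear interpolation through the points of the other
    system sizes within the same branch; u values within snap_tol of a node
    are treated as exact matches (keeps a perfect collapse at exactly zero).
    Returns (sum of weighted squared residuals, number of points used).
    """
    n = u.shape[0]
    total = 0.0
    n_used = 0
    for kk in range(n_k):
        for dd in range(n_d):
            # gather "other" points: same branch, different size
            cnt = 0
            for i in range(n):
                if k_id[i] == kk and d_id[i] != dd:
                    cnt += 1
            if cnt < 2:
                continue
            uo = np.empty(cnt)
            wo = np.empty(cnt)
            so = np.empty(cnt)
            j = 0
            for i in range(n):
                if k_id[i] == kk and d_id[i] != dd:
                    uo[j] = u[i]
                    wo[j] = w[i]
                    so[j] = s2[i]
                    j += 1
            order = np.argsort(uo)
            uo = uo[order]
            wo = wo[order]
            so = so[order]
            for i in range(n):
                if k_id[i] != kk or d_id[i] != dd:
                    continue
                ui = u[i]
                if ui < uo[0] or ui > uo[cnt - 1]:
                    continue
                # rightmost interval with uo[j] <= ui
                lo = 0
                hi = cnt - 1
                while hi - lo > 1:
                    mid = (lo + hi) // 2
                    if uo[mid] <= ui:
                        lo = mid
                    else:
                        hi = mid
                du = uo[lo + 1] - uo[lo]
                tol = snap_tol * (1.0 + abs(ui))
                if abs(ui - uo[lo]) <= tol or du <= 0.0:
                    w_hat = wo[lo]
                    var_hat = so[lo]
                elif abs(uo[lo + 1] - ui) <= tol:
                    w_hat = wo[lo + 1]
                    var_hat = so[lo + 1]
                else:
                    lam = (ui - uo[lo]) / du
                    w_hat = (1.0 - lam) * wo[lo] + lam * wo[lo + 1]
                    var_hat = (1.0 - lam) ** 2 * so[lo] + lam * lam * so[lo + 1]
                diff = w[i] - w_hat
                total += diff * diff / (s2[i] + var_hat)
                n_used += 1
    return total, n_used


@njit(cache=True)
def run_mc_kernel(r, th, z, xi, R, D, H, n_sweeps, sample_stride,
                  p_local, p_cent, step_local, tune, rng,
                  n_bins, collect, resync_every, n_profile_blocks,
                  store_positions):
    """Metropolis chain: local, centrifugal and condensed<->unbound swap moves.

    Mutates (r, th, z) in place.  One sweep = N attempted moves.  When
    `collect`, records energy and condensed count every `sample_stride` sweeps
    and accumulates the ln(r/R) histogram into `n_profile_blocks` sequential
    blocks (for blocking error bars on the profile).  When `tune`, step_local
    is adapted every 50 sweeps toward ~40% local acceptance (equilibration
    only; tuning during production would break detailed balance).
    """
    N = r.shape[0]
    delta = math.log(D / R)
    rstar = math.sqrt(R * D)  # ln(r*/R) = Delta/2 midpoint criterion
    two_pi = 2.0 * math.pi

    energy = total_energy_kernel(r, th, z, xi, R, H)

    n_samples = n_sweeps // sample_stride if collect else 0
    energies = np.empty(n_samples)
    counts = np.zeros(n_samples, dtype=np.int64)
    hist = np.zeros((n_profile_blocks, n_bins))
    r_samples = np.empty((n_samples if store_positions else 0, N))
    attempted = np.zeros(3, dtype=np.int64)
    accepted = np.zeros(3, dtype=np.int64)
    tune_att = 0
    tune_acc = 0
    sample_idx = 0

    for sweep in range(n_sweeps):
        for _step in range(N):
            u = rng.random()
            if u < p_local:
                mt = 0
            elif u < p_local + p_cent:
                mt = 1
            else:
                mt = 2
            attempted[mt] += 1

            if mt == 0:
                i = rng.integers(0, N)
                tune_att += 1
                ok, rp, thp, zp = propose_local_kernel(
                    rng, r[i], th[i], z[i], step_local, R, D, H)
                if not ok:
                    continue
                de = (xi * (one_ion_pair_sum(r, th, z, i, rp, thp, zp, H)
                            - one_ion_pair_sum(r, th, z, i, r[i], th[i], z[i], H))
                      + 2.0 * xi * math.log(rp / r[i]))
                if _metropolis_accept(rng, -de):
                    r[i] = rp
                    th[i] = thp
                    z[i] = zp
                    energy += de
                    accepted[0] += 1
                    tune_acc += 1
            elif mt == 1:
                i = rng.integers(0, N)
                rp, thp, zp = propose_centrifugal_kernel(rng, R, delta, H)
                de = (xi * (one_ion_pair_sum(r, th, z, i, rp, thp, zp, H)
                            - one_ion_pair_sum(r, th, z, i, r[i], th[i], z[i], H))
                      + 2.0 * xi * math.log(rp / r[i]))
                # Hastings ratio: (r'/r) from the cylindrical volume element and
                # (r'/r) from the 1/r log-uniform proposal density -> (r'/r)^2
                ln_acc = -de + 2.0 * math.log(rp / r[i])
                if _metropolis_accept(rng, ln_acc):
                    r[i] = rp
                    th[i] = thp
                    z[i] = zp
                    energy += de
                    accepted[1] += 1
            else:
                nc = 0
                for j in range(N):
                    if r[j] <= rstar:
                        nc += 1
                if nc == 0 or nc == N:
                    continue  # skipped, counted as rejected
                kc = rng.integers(0, nc)
                ku = rng.integers(0, N - nc)
                ia = -1
                ib = -1
                cc = 0
                cu = 0
                for j in range(N):
                    if r[j] <= rstar:
                        if cc == kc:
                            ia = j
                        cc += 1
                    else:
                        if cu == ku:
                            ib = j
                        cu += 1
                ra_new = r[ib]
                rb_new = r[ia]
                # one-body log terms cancel exactly for a radius exchange
                de = xi * (two_ion_pair_sum(r, th, z, ia, ib, ra_new, rb_new, H)
                           - two_ion_pair_sum(r, th, z, ia, ib, r[ia], r[ib], H))
                if _metropolis_accept(rng, -de):
                    r[ia] = ra_new
                    r[ib] = rb_new
                    energy += de
                    accepted[2] += 1

        if tune and (sweep + 1) % 50 == 0 and tune_att > 0:
            acc_frac = tune_acc / tune_att
            step_local *= math.exp(0.7 * (acc_frac - 0.4))
            lo = 1e-4 * (D - R)
            hi = 2.0 * max(D, H)
            if step_local < lo:
                step_local = lo
            if step_local > hi:
                step_local = hi
            tune_att = 0
            tune_acc = 0

        if resync_every > 0 and (sweep + 1) % resync_every == 0:
            energy = total_energy_kernel(r, th, z, xi, R, H)

        if collect and (sweep + 1) % sample_stride == 0 and sample_idx < n_samples:
            energies[sample_idx] = energy
            c = 0
            blk = sample_idx * n_profile_blocks // n_samples
            for j in range(N):
                if r[j] <= rstar:
                    c += 1
                b = int(math.log(r[j] / R) / delta * n_bins)
                if b < 0:
                    b = 0
                if b >= n_bins:
                    b = n_bins - 1
                hist[blk, b] += 1.0
            counts[sample_idx] = c
            if store_positions:
                for j in range(N):
                    r_samples[sample_idx, j] = r[j]
            sample_idx += 1

    return energies, counts, hist, attempted, accepted, step_local, energy, r_samples
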