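"""Metropolis Monte Carlo chains for the cylindrical cell model.

Three move types:

* local — uniform displacement in a Cartesian cube (half-width auto-tuned
  during equilibration to ~40% acceptance, then frozen);
* centrifugal — log-uniform radial resampling r' = R exp(u Delta) with fresh
  theta and z; the Metropolis-Hastings ratio carries the factor (r'/r)^2
  (one power of r'/r from the cylindrical volume element, one from the 1/r
  proposal density), validated by detailed-balance tests against exact
  one-ion marginals;
* global swap — exchange the radial coordinates of one condensed
  (ln(r/R) <= Delta/2) and one unbound ion; symmetric proposal, plain
  Metropolis.  This large-scale move makes equilibration independent of the
  initial condition.

One sweep = N attempted moves regardless of type.  Chains are bit-reproducible
for a fixed seed (single Philox stream per chain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import CellModel, IonConfiguration

__all__ = ["RunConfig", "ChainResult", "run_chain", "initial_configuration",
           "propose_local", "propose_centrifugal", "propose_global_swap"]


@dataclass(frozen=True)
class RunConfig:
    """Protocol of a single MC chain."""

    seed: int = 0
    n_equil: int = 2000
    n_prod: int = 10000
    sample_stride: int = 10
    move_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    step_local: float = 1.0
    n_bins: int = 100
    init: str = "random"          # "random" | "condensed" | "unbound"
    resync_every: int = 2000      # sweeps between cached-energy recomputations
    n_profile_blocks: int = 32
    store_positions: bool = False

    def __post_init__(self):
        if self.n_equil < 0 or self.n_prod <= 0 or self.sample_stride <= 0:
            raise ValueError("invalid sweep counts")
        mm = self.move_mix
        if len(mm) != 3 or any(p < 0 for p in mm) or abs(sum(mm) - 1.0) > 1e-12:
            raise ValueError("move_mix must be 3 nonnegative probabilities summing to 1")
        if self.step_local < 0:
            raise ValueError("step_local must be nonnegative")
        if self.init not in ("random", "condensed", "unbound"):
            raise ValueError("init must be 'random', 'condensed' or 'unbound'")


@dataclass
class ChainResult:
    """Samples and provenance of one production run."""

    energies: np.ndarray           # beta*H at each sample (k_B T)
    condensed_counts: np.ndarray   # ions with ln(r/R) <= Delta/2 at each sample
    profile_histogram: np.ndarray  # (n_profile_blocks, n_bins) counts in ln(r/R)
    bin_edges: np.ndarray          # n_bins+1 edges in ln(r/R) over [0, Delta]
    acceptance: dict               # per move type: attempted / accepted
    seed: int
    model: CellModel
    run_config: RunConfig
    step_local_used: float
    final_config: IonConfiguration
    r_samples: np.ndarray | None = None   # (n_samples, N) when requested

    @property
    def n_samples(self) -> int:
        return self.energies.shape[0]


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def initial_configuration(model: CellModel, rng: np.random.Generator,
                          init: str = "random") -> IonConfiguration:
    """Draw a starting configuration.

    "random": log-uniform radii over the whole cell (mixed state);
    "condensed"/"unbound": log-uniform over the inner/outer half only —
    exposed for the equilibration-independence test the swap move exists for.
    """
    N, delta = model.N, model.delta
    u = rng.random(N)
    if init == "random":
        x = u * delta
    elif init == "condensed":
        x = u * (delta / 2)
    elif init == "unbound":
        x = delta / 2 + u * (delta / 2)
    else:
        raise ValueError(init)
    r = model.R * np.exp(x)
    theta = rng.random(N) * 2.0 * np.pi
    z = rng.random(N) * model.H
    return IonConfiguration(r, theta, z)


def propose_local(config: IonConfiguration, i: int, step_local: float,
                  rng: np.random.Generator, model: CellModel):
    """Candidate position for a local cube move; None if it leaves [R, D]."""
    if not (0 <= i < config.N):
        raise IndexError("ion index out of range")
    ok, rp, thp, zp = _kernels.propose_local_kernel(
        rng, config.r[i], config.theta[i], config.z[i], step_local,
        model.R, model.D, model.H)
    return (rp, thp, zp) if ok else None


def propose_centrifugal(config: IonConfiguration, i: int,
                        rng: np.random.Generator, model: CellModel):
    """Log-uniform radial candidate with fresh theta, z.

    The matching acceptance rule is min{1, exp(-dE) * (r'/r)^2}.
    """
    if not (0 <= i < config.N):
        raise IndexError("ion index out of range")
    return _kernels.propose_centrifugal_kernel(rng, model.R, model.delta, model.H)


def propose_global_swap(config: IonConfiguration, model: CellModel,
                        rng: np.random.Generator):
    """Pick one condensed and one unbound ion; return (i_cond, i_unb, r_i', r_j').

    None when one side is empty (move skipped, counted as rejected by the
    chain driver).  The exchange keeps theta and z, so the one-body log terms
    cancel and the proposal is symmetric (plain Metropolis acceptance).
    """
    cond = np.flatnonzero(config.r <= model.r_star)
    unb = np.flatnonzero(config.r > model.r_star)
    if cond.size == 0 or unb.size == 0:
        return None
    ia = int(cond[rng.integers(0, cond.size)])
    ib = int(unb[rng.integers(0, unb.size)])
    return ia, ib, float(config.r[ib]), float(config.r[ia])


def run_chain(model: CellModel, run: RunConfig, lekner=None) -> ChainResult:
    """Equilibrate, then sample a production chain.

    Deterministic for a fixed (seed, version): the equilibration and
    production phases consume a single Philox stream.  Aborts on non-finite
    energy.
    """
    rng = _rng(run.seed)
    config = initial_configuration(model, rng, run.init)
    r, th, z = config.r, config.theta, config.z
    p_local, p_cent, _p_swap = run.move_mix
    step = run.step_local

    if run.n_equil > 0:
        *_ignored, step, e_eq, _rs = _kernels.run_mc_kernel(
            r, th, z, model.xi, model.R, model.D, model.H,
            run.n_equil, run.sample_stride, p_local, p_cent, step,
            True, rng, run.n_bins, False, run.resync_every,
            run.n_profile_blocks, False)
        if not math.isfinite(e_eq):
            raise RuntimeError("non-finite energy during equilibration")

    energies, counts, hist, att, acc, step, e_fin, r_samples = _kernels.run_mc_kernel(
        r, th, z, model.xi, model.R, model.D, model.H,
        run.n_prod, run.sample_stride, p_local, p_cent, step,
        False, rng, run.n_bins, True, run.resync_every,
        run.n_profile_blocks, run.store_positions)
    if not np.all(np.isfinite(energies)):
        raise RuntimeError("non-finite energy during production")

    acceptance = {
        name: {"attempted": int(att[k]), "accepted": int(acc[k]),
               "rejected": int(att[k] - acc[k])}
        for k, name in enumerate(("local", "centrifugal", "swap"))
    }
    final = IonConfiguration(r, th, z, energy=float(e_fin))
    return ChainResult(
        energies=energies,
        condensed_counts=counts,
        profile_histogram=hist,
        bin_edges=np.linspace(0.0, model.delta, run.n_bins + 1),
        acceptance=acceptance,
        seed=run.seed,
        model=model,
        run_config=run,
        step_local_used=float(step),
        final_config=final,
        r_samples=r_samples if run.store_positions else None,
    )
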