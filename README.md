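# cylcond

Monte Carlo and theory toolkit for **counterion condensation on a charged
cylinder** — the Manning transition and the complete-condensation transition
that appears when the cylinder radius shrinks with the cell size.

## The problem

A stiff polyelectrolyte is modeled as an infinite cylinder of radius *R* and
line charge density *τ*, coaxial inside an outer cell of radius *D*, with *N*
neutralizing pointlike counterions of valency *q* in between (salt-free cell
model). The competition between the logarithmic electrostatic attraction and
the confinement entropy produces a condensation transition in the
infinite-dilution limit Δ = ln(*D*/*R*) → ∞: above the critical Manning
parameter ξ = *q*ℓ_B*τ* = 1 a finite fraction *f* of counterions stays bound
to the rod. Mean-field (Poisson–Boltzmann, PB) theory predicts a continuous
transition with *f* → 1 − 1/ξ, while strong-coupling (SC) theory predicts a
discontinuous all-or-nothing jump at the same point. The two pictures are
reconciled by a *second* continuous transition into a completely condensed
state (*f* = 1): approaching *R* → 0 and *D* → ∞ along the schedule
*R*/*a* ~ (*D*/*a*)^−α (with *a* = *q*/*τ*), complete condensation sets in at

    ξ₂ ≈ 1 + 1/α ,      equivalently  ξ₂ = 1 − ln D̃ / ln R̃ ,

which merges with the Manning point as α → ∞ (the SC discontinuity) and
escapes to infinity as α → 0 (the mean-field picture). The coupling parameter
at onset is Ξ ≈ ξ₂² exp(Δ/ξ₂).

The package provides, in reduced units (lengths in *a*, energies in k_BT):

* **model / sampling** — the reduced Hamiltonian
  βH = ξ Σ_{i<j} v(ρ_ij, ζ_ij; H) + 2ξ Σ_i ln(r_i/R) with the 1D-periodic
  Coulomb factor *v* evaluated by a Lekner–Sperb-type resummation, and a
  Metropolis engine (numba-compiled) with local, centrifugal (log-uniform
  radial) and condensed↔unbound swap moves;
* **observables** — condensed fraction *f* (counting ions inside the
  log-midpoint cut ln(r*/R) = Δ/2), dimensionless heat capacity
  C̃ = ⟨(δH)²⟩/N, rescaled radial profiles ρ̃(r), all with
  Flyvbjerg–Petersen blocking errors;
* **theory** — PB cell-model solver (shooting in ln r), SC two-state fraction
  and single-particle profile, needle-limit profile
  ρ̃(r) = 2(1 − 1/ξ)²(R/r)^2ξ, the onset formulas above, and the
  two-configuration free-energy argument behind them;
* **scaling** — finite-size scaling: power-law fits m ~ Δ^−β/ν and
  two-parameter data collapse m = Δ^−β/ν m̃(Δ^{1/ν}ζ) with bootstrap errors;
* **oracle** — brute-force image-sum oracles and synthetic fixtures that make
  everything testable without external data.

## Worked example

```python
import cylcond as cc

model = cc.CellModel.from_alpha(N=20, xi=1.6, alpha=1.0, delta=8.0)
chain = cc.run_chain(model, cc.RunConfig(seed=1, n_equil=5_000,
                                         n_prod=20_000, sample_stride=10))
summ = cc.summarize(chain, model)
print(summ.f, summ.f_err, summ.C_tilde, summ.C_err)
```

prints (seed 1):

```
condensed fraction  f  = 0.578 +- 0.002
heat capacity       C~ = 15.84 +- 0.59
```

ξ = 1.6 lies between the Manning point ξ₁ = 1 and the complete-condensation
point ξ₂ = 2 (α = 1), so the cell is partially condensed — 58% of the ions
sit inside the midpoint cut — and the energy fluctuations are large, the
hallmark of the disordered window between the two ordered regimes. The
scripts in `examples/` walk through each capability (pair potential vs
brute-force oracle, PB theory and onset formulas, a ξ sweep showing both
transitions, exponent recovery by data collapse) and print a line explaining
what the numbers mean.

A thin CLI mirrors the library: `cylcond simulate|analyze|theory|collapse|
fixtures|grid` (see `cylcond --help`); results are plain CSV plus a JSON
manifest with the full parameter echo and seeds.

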