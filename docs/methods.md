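# Methods

## Model and units

A uniformly charged cylinder (radius R, line charge density τ > 0) lies on
the axis of a cylindrical cell of radius D; N pointlike counterions of
valency q move in the annulus R ≤ r ≤ D. The box of height H is periodic in
z. Image-charge (dielectric) effects, added salt and ion structure are
outside the scope of the package.

All lengths are measured in a = q/τ (the spacing of counterions neutralizing
the rod as a 1D lattice) and energies in k_BT. Charge neutrality then fixes
H = N, and ℓ_B q² = ξ·a with ξ = q ℓ_B τ the Manning parameter, so the
reduced Hamiltonian is

    βH = ξ Σ_{i<j} v(ρ_ij, ζ_ij; H) + 2ξ Σ_i ln(r_i / R).

The one-body logarithm is the bare-rod attraction; the periodic images of the
rod's line charge are already implied by it. The interaction of an ion with
its own periodic replicas is independent of position (images displaced by nH
in z only) and is dropped: it cancels in all energy differences and in the
energy variance. Derived couplings: Ξ = ξ²·(a/R), Gouy–Chapman length
μ = R/ξ.

## Periodic pair potential

The image sum Σ_n 1/√(ρ² + (ζ + nH)²) is conditionally divergent; only
differences between two geometries are physical. The package fixes the
additive constant by the convention C₀ = 0 of the Bessel form

    v(ρ, ζ; H) = (2/H)[ 2 Σ_{n≥1} K₀(2πnρ/H) cos(2πnζ/H) − ln(ρ/H) ].

Two evaluators share this constant exactly and can be mixed freely:

* the K₀ series, truncated when the Bessel factor drops below the requested
  tolerance (`LeknerParams`: n_fourier cap, rho_switch, tol) — efficient
  except near the axis;
* a Sperb-style direct scheme used everywhere by the Monte Carlo kernels:
  the nearest 24 image pairs are summed explicitly and the remainder by
  Euler–Maclaurin with the exact tail integral (antiderivative of the
  subtracted summand) and analytic derivative corrections through fifth
  order. The identity linking the two representations carries the constant
  2γ − 2 ln 2, which is included. For ρ ≥ 2H the series needs only 2–3
  terms, evaluated from the large-argument asymptotic expansion of K₀.

Uniform accuracy is ~1e−12 absolute (verified against the K₀ series with
scipy and mpmath, and — in differences — against a brute-force image sum
with two-step Richardson extrapolation, the package's independent oracle).
The degenerate point ρ = 0 with ζ off the image planes is handled exactly;
ρ = 0 on an image plane (self-overlap) raises.

## Monte Carlo

Metropolis sampling with three move types (default mix 0.6 / 0.3 / 0.1):

* **local** — uniform displacement in a Cartesian cube of half-width s; s is
  tuned toward ~40% acceptance every 50 sweeps during equilibration only and
  frozen for production (tuning during production would violate detailed
  balance). Proposals leaving [R, D] count as attempted-and-rejected.
* **centrifugal** — r′ = R e^{uΔ} with u ~ U(0,1), fresh θ and z. The
  Metropolis–Hastings ratio carries (r′/r)²: one power from the cylindrical
  volume element r dr dθ dz, one from the 1/r proposal density. Correctness
  is tested against exact one-ion marginals (χ² and KS at ξ = 2 and ξ = ½)
  and quadrature means, not assumed.
* **global swap** — one condensed ion (ln(r/R) ≤ Δ/2, the same midpoint
  criterion used by the observable) and one unbound ion exchange radial
  coordinates; θ and z are kept, so the one-body log terms cancel and the
  proposal is symmetric. This move makes equilibration independent of an
  all-condensed vs all-unbound start, which is tested directly.

One sweep = N attempted moves. A chain consumes a single Philox stream, so
results are bit-reproducible per (seed, version); grid drivers derive child
seeds through SeedSequence spawning. The cached energy is advanced by move
deltas and resynchronized against a from-scratch recomputation every 2000
sweeps (configurable; drift without resync stays below 1e−9 relative over
10⁴ sweeps, which is asserted in the tests). Initial radii are log-uniform
(mixed state) by default; ordered "condensed"/"unbound" starts exist for the
equilibration test.

## Observables

* **Condensed fraction** f: mean count of ions with ln(r/R) ≤ Δ/2 divided by
  N. Counting is used rather than integrating the binned profile to avoid
  binning bias; with a bin-aligned cut the two estimators coincide exactly
  and this is cross-checked. Ties (r = r*) count as condensed; the event has
  measure zero.
* **Heat capacity** C̃ = ⟨(δH)²⟩/N with 1/n variance normalization (fixed,
  for bit-reproducibility; immaterial at production sample counts).
* **Radial profile**: histogram in ln(r/R) (default 100 bins over [0, Δ]),
  converted to number density via the exact shell volume π(r₊² − r₋²)H and
  rescaled to ρ̃ = ρ·2πR²/ξ (equivalently ρ/(2π ℓ_B σ²)). Neutrality —
  the integrated charge fraction equals 1 — is asserted on every profile.
* **Errors**: Flyvbjerg–Petersen blocking. The plateau is taken as the
  largest standard-error estimate among levels retaining ≥ 16 blocks, a
  robust proxy for the short series used in tests. The heat-capacity error
  blocks the centered-squared series, a first-order approximation for the
  variance of a variance under autocorrelation (recorded in the output
  manifest). Profile errors come from 32 sequential sample blocks.

## Poisson–Boltzmann cell model

In x = ln(r/R) the salt-free PB equation becomes u″(x) = −A e^{2x−u}, where
u is the reduced potential energy of a counterion (u = 2ξx at the bare rod)
and the counterion density is n ∝ e^{−u}. Gauss's law gives the boundary
conditions u′(0) = 2ξ and u′(Δ) = 0 and the cumulative condensed fraction
f(x) = 1 − u′(x)/(2ξ), hence f(0) = 0 and f(Δ) = 1 identically. The
normalization A is the single shooting parameter: integrating w = u − 2x with
solve_ivp (RK45, rtol 1e−10) and locating the neutrality residual's root in
ln A by Brent's method on [−800, 20]. The residual is monotone in A, making
the bracket robust for ξ up to ~10² and Δ up to ~200; the log coordinate is
what keeps Δ = 100 tractable. The solver is validated against an independent
solve_bvp solution, the large-Δ Manning limit f → 1 − 1/ξ (reached to 1e−12
at ξ = 2, Δ = 40), and profile neutrality by quadrature.

**Threshold location.** At finite Δ the PB midpoint fraction is smooth, so
the infinite-dilution threshold is estimated in two steps: f_mid(ξ, Δ) is
computed for Δ ∈ {10, 20, 40} and extrapolated pointwise to 1/Δ → 0 with the
quadratic in 1/Δ exactly determined by the three sizes; the onset is then the
zero crossing of a straight line fitted to the extrapolated order parameter
over the small-f window [0.02, 0.15] (the standard order-parameter-root
locator; extrapolating fixed-level crossings instead is visibly curved in
1/Δ and biased by ~0.07 at these sizes). The estimate lands at 1.002.

## Complete-condensation formulas

The onset formulas ξ₂(α) = 1 + 1/α and ξ₂ = 1 − ln D̃/ln R̃ (with
R̃ = c·D̃^−α, c defaulting to 1 and exposed), the onset coupling
Ξ = ξ₂² e^{Δ/ξ₂}, and the radius schedule ln(R/a) = −αΔ/(α+1) are direct
implementations; α = 0 and α = ∞ are handled as explicit limits.

The two-configuration free-energy argument compares a fully condensed 1D
lattice with a state in which one ion sits at the outer boundary.
`lattice_energies` evaluates the printed single-period sums (ℓ = 1 … N−1).
Individually these sums diverge with the periodic images; the *difference*
converges, and `free_energy_difference` therefore extends it over all images:
U_a − U_b = 2ξ S(x) with x = ND/H = D/a and S(x) = Σ_{ℓ≥1}(1/ℓ −
1/√(x²+ℓ²)), evaluated with an analytic Euler–Maclaurin tail. The sign is
fixed so that ΔF = F(boundary ion) − F(condensed) = 2(ξ−1)ln(D/R) − 2ξS(x),
whose root in ξ reproduces the logarithmic-ratio onset formula; both the
affine "exact-sum" and asymptotic (S → ln x) roots are exposed. Note that
S(x) − ln x → γ − ln 2 ≈ −0.116 as x → ∞ (approached like ln(x)/x): the
logarithmic estimate is a leading-order approximation whose relative error
at x = 100 is 2.4% and falls below 1% only for x ≳ 10⁵. The package reports
the converged sum; the affected onset roots inherit only an O(1/ln) shift
(≲ 0.3% at Δ = 100).

## Finite-size scaling

Order parameters m₁ = f (Manning branch) and m₂ = 1 − f (complete
condensation) are analyzed under m_k = Δ^{−β/ν} m̃_k(Δ^{1/ν} ζ_k) with
ζ_k = 1 − ξ_k/ξ and ξ_k fixed at the theoretical critical points (a fit-ξ_c
mode is deliberately absent from the default path).

* `exponent_ratio_fit`: weighted least squares of ln m vs ln Δ at (or
  interpolated to) the critical point; errors by parametric bootstrap
  (records perturbed by their quoted errors — with one point per size,
  resampling records would produce degenerate designs).
* `data_collapse`: for trial (β, ν) all points are transformed to
  (u, w) = (Δ^{1/ν}ζ, Δ^{β/ν}m) and each point is compared against the
  linear interpolation through the other sizes' transformed points, with the
  interpolant's propagated variance added to the point's own. This
  interpolation-residual objective (Houdayer–Hartmann style) needs no
  smoothing bandwidth and is exactly zero for a perfect collapse
  (coincidences within a 1e−9 relative snap tolerance count as exact nodes).
  Optimization: 15×15 coarse grid on (β, ν) ∈ [0.4, 1.8]×[0.5, 2.2], then
  Nelder–Mead; an explicit check rejects datasets whose transformed windows
  overlap nowhere. Bootstrap: records resampled with replacement, refits
  warm-started from the optimum (200 reps default).

**Error convention.** Reported exponent errors are half-widths of central
95% percentile bootstrap intervals. Recovery calibration on the synthetic
fixture (logistic scaling function, β = 0.98, ν = 1.11, Δ ∈ {20…100}, 3%
multiplicative Gaussian noise) covers the truth in ~100/100 seeded trials
for both exponents, and 95/100 for the power-law ratio fit at 2% noise.

## Synthetic data

`synthetic_collapse_data` draws m = clip(Δ^{−β/ν} g(Δ^{1/ν}ζ)(1+ε), 0, 1)
with logistic g and ε ~ N(0, noise_sd²), deterministic per seed; quoted
errors are noise_sd·m_model (floor 1e−4·m_model when noiseless, since the
objective weights by them). The default ζ window (±0.12, 17 points per size)
guarantees overlapping transformed ranges for ν near 1. A `coincident` mode
places per-size ξ grids so the scaling variable is identical across sizes —
used by the exact-collapse tests. What the generator does *not* emulate:
autocorrelated MC noise, error underestimation, corrections to scaling, and
uncertainty in ξ_c; passing recovery tests therefore demonstrates the
machinery, not the absence of those systematics in real chain data.

## Problem sizes and defaults

Package defaults chosen for the desk-scale study conditions:

* dual-transition sweep: α = 1, Δ = 10, N = 30, twelve ξ ∈ [0.6, 3.0],
  2·10⁴ equilibration + 8·10⁴ production sweeps per point, stride 10. At
  this size the two transitions appear as a monotone rise of f from ~0.01
  (ξ = 0.6) to ~0.997 (ξ = 3) with C̃ elevated only in between; the sharp
  thermodynamic-limit features require Δ ~ 100 and N ~ 300, which the
  formulas and the scaling machinery cover analytically.
* sampler-exactness checks: 10⁶ retained samples (stride 10) on one-ion
  cells; stride and a centrifugal-heavy move mix keep residual
  autocorrelation small enough for classical χ²/KS p-values.
* brute-force oracle: cutoff M = 4096 with two Richardson steps; the
  returned error estimate is validated against cutoff doubling.

## Known limitations

* The heat-capacity error bar is a blocking estimate on the squared
  fluctuations, adequate for the qualitative C̃(ξ) assertions made here but
  not for high-precision variance inference.
* The collapse objective assumes the master curve is locally linear between
  neighboring transformed points; very sparse ξ grids bias it (mitigated by
  the denser default grids).
* Near-degenerate geometries (Δ ≲ 1e−3) make the centrifugal move a pure
  angular resampling; this limit is tested but not optimized.
* fastmath is off in all kernels; bit-reproducibility is per numba version
  and platform.
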