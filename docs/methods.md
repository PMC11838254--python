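# Methods

## Model

A fibril is a linear lattice of N equivalent sites. Site states are empty,
radioligand (L), or inhibitor (I). A configuration's statistical weight is
the product over sites of activities — 1 for empty, [L]/K_D for L, [I]/K_I
for I — times, over nearest-neighbor bonds, the stacking factors α_L (L–L),
α_I (I–I), χ (L–I); bonds involving an empty site contribute 1. Stacking
factors relate to energies by α = exp(−C/k_B T). Energies are additive and
strictly nearest-neighbor; couplings beyond adjacent sites, secondary binding
sites, inter-protofilament lattices, ligand depletion, and binding kinetics
are all outside the model.

Energy units are kcal/mol with k_B = 1.987204259e−3 kcal/(mol K), and "room
temperature" is taken as T = 298.15 K. Any temperature in 293–310 K rounds
−k_B T ln 10 to −1.4 kcal/mol at two significant figures, so this choice is
not load-bearing; it is exposed through `ThermoContext`.

## Closed forms (`isotherms`)

The infinite-lattice saturation isotherm and the saturated competition
isotherm are largest-eigenvalue results for the 2-state transfer matrix;
both are implemented directly with their degenerate limits defined by
continuity (c = 0 gives f = 0; the β = 0, x = 1 discriminant zero gives
f = 1/2 by log-symmetry). Useful identities, all tested: particle–hole
symmetry f(c) + f(1/(α²c)) = 1; competition log-symmetry f(x) + f(1/x) = 1;
midpoint log-slopes √α/4 and −1/(4√β).

The biphasic "plateau transition" is operationalized as the sign change of
the third derivative of f_L with respect to ln x at the midpoint:
d³f/d(ln x)³ = −(β − 3)/(16 β^{3/2}) there, so the sign flips at β = 3 —
below it the center is the steepest part of the curve, above it the curve
flattens mid-descent. `midpoint_log_derivative` evaluates first and third
log-derivatives by central differences (base step 0.01 in ln x) with one
Richardson extrapolation; with f analytic this gives ~1e−8 absolute accuracy
for the third derivative, and results are step-size stable (tested over a
2× step sweep). `critical_beta` brackets the sign change with Brent's method
on (1.5, 9).

## Exact lattice statistics (`lattice`)

The transfer matrix uses the symmetric convention
T(s,s′) = √w_s · p(s,s′) · √w_s′, so it is real-symmetric: the principal
eigenpair comes from a standard symmetric eigensolve, the bulk site marginal
is the squared principal-eigenvector component (equivalent to the
Hellmann–Feynman derivative w_s ∂ln λ/∂w_s), and bond probabilities are
v_a T(a,b) v_b/λ.

Finite free-ended chains use boundary vectors of √w and left/right partial
products renormalized at every site, so partition functions that would
overflow doubles are never formed; site and bond marginals are ratios in
which the normalizations cancel. Periodic chains use the eigendecomposition
with eigenvalues scaled by λ_max. A single site (either boundary) has no
bonds; its pair fractions are `None`. Everything is validated against a
brute-force enumeration oracle (guarded at 10⁶ configurations) to 1e−12.

Bound-count distributions P(n = k) come from dynamic programming over
(site, state, count), renormalized per site; for periodic chains the ring is
closed by conditioning on the first site's state, with per-chain log
normalizations tracked so the branches recombine correctly. The
non-cooperative 2-state case reproduces Binomial(N, [L]/(K_D+[L])) to
1e−10.

### MCMC

The sampler is single-site heat-bath (Gibbs): each site is redrawn from its
exact conditional distribution given its two neighbors. Sites are updated in
checkerboard (even/odd) order — same-parity sites are conditionally
independent under nearest-neighbor coupling, so each half-sweep is an exact
block Gibbs update and vectorizes over the lattice. One sweep = N site
updates. The run is fully determined by an integer seed
(`numpy.random.default_rng`). Defaults (5000 sweeps, 1000 burn-in, thinning
10) comfortably produce estimates within 3 batch-means standard errors of
the exact finite-N transfer-matrix values at N = 1000 across the tested
(c, α) grid; standard errors use ~20 equal batches of the thinned trace.
The sampler exists as a cross-check of the exact methods (and for regimes
where one might extend the model), not as the primary computational route.

The saturated 3-state → 2-state reduction is verified numerically rather
than assumed: `saturating_limit_check` evaluates the full 3-state infinite
lattice with both activities scaled by 10²–10⁶ and shows monotone
convergence of the radioligand share of occupied sites to the closed-form
competition isotherm.

## Fitting (`fitting`)

Model fits are bounded nonlinear least squares (lmfit/`least_squares`) with
five seeded starts spread over the cooperativity axis, since the
(K_D, α_L) objective has a long shallow valley. K_D, α_L, B_max (and IC50,
β) are fitted on the natural-log scale, which conditions that valley;
solver tolerances are 1e−14 because the valley floor is flat to ~1e−8.
Saturation fits default to relative-error weighting (residuals divided by
the model value, floored at 10⁻³ B_max), matching counting-type noise whose
spread scales with signal; ordinary least squares is available. Standard
errors come from the Jacobian covariance; confidence intervals for
log-fitted parameters are computed on the log scale and exponentiated
(asymmetric, positivity-respecting). These Wald-log intervals measured
indistinguishable calibration from profile-likelihood intervals on the
recovery benchmark at a fraction of the cost.

The effective Hill coefficient of a theoretical isotherm is protocol-pinned,
because fitted steepness depends on the fitted range: 200 log-spaced points
spanning fractional occupancy 0.01–0.99 (window found by root bracketing),
unweighted least squares of the ascending or descending Hill form. Under
this protocol the α_L = 10 saturation isotherm fits n ≈ 2.75; the midpoint
log-slope alternative (n_slope = √α_L, here 3.16) is a distinct, sharper
measure and both are available.

Identifiability is a feature of the science, not a fitting defect: a
saturated competition assay determines only (IC50, β), so `fit_competition`
estimates exactly those, and `identifiability_profile` walks the
(K_D, α_L) ridge at fixed ratio — flat to < 1e−8 relative for competition
data, visibly curved for wide-range saturation data, whose steepness breaks
the degeneracy. Midpoint-only saturation designs show the same ridge as a
near-unit (log K_D, log α_L) correlation with inflated uncertainties.

### Synthetic data and the recovery benchmark

The generator produces CPM = B_max·f + ns·[L] + baseline with seeded
Gaussian noise, absolute or proportional; negative noisy CPM values are kept
so low-signal fits stay unbiased. The parameter-recovery benchmark uses
K_D = 1 nM, α_L = 10, B_max = 1000 CPM, 5 % proportional noise, and 12
log-spaced concentrations from 1 pM to 100 nM — a realistic saturation
design centered on the EC50 of 0.1 nM with ~1.5 decades of margin on both
sides. Across 100 seeded replicates each parameter's nominal-95 % interval
covers its generating value ≥ 90 % of the time (measured 93/97/95 for
K_D/α_L/B_max). Joint coverage of all three intervals at once is nominally
lower (~88 %), as expected for simultaneous marginal intervals.

What the generator does not emulate: ligand depletion, Poisson counting
statistics (noise is Gaussian), plate effects, or the brain-homogenate
heterogeneity of real ex vivo assays — passing recovery tests show the
estimator is calibrated under the stated noise model, not that real tau
data will be as kind.

## Detection (`detection`)

Unit convention: M is counts per unit time per unit volume and every fibril
at concentration [F] contributes λ·n_L, so n_C = M/(λ[F]) and only ratios
matter. Both detection criteria are exposed: the time-averaged mean
criterion ⟨n_L⟩ ≥ n_C (measurement slower than binding equilibration),
whose non-cooperative boundary reproduces [L]_min = K_D·n_C/(N − n_C)
exactly, and the instantaneous tail probability P(n_L ≥ n_C) from the exact
count distribution (n_C > N returns probability 0 rather than an error).
At matched mean occupancy, stacking clusters the bound sites and widens the
count distribution, fattening both tails.

## Problem sizes

Default test and acceptance runs use N ≤ 10⁴ for exact finite lattices,
N = 1000 with 5000 sweeps for the MCMC comparison, enumeration up to 3⁸
states, and 100-replicate fitting benchmarks — sizes chosen so the entire
suite runs in well under a minute of CPU while leaving every comparison
statistically decisive.

## Known limitations

* The general (unsaturated) 3-state competition model is computed exactly
  but not fitted to data; its eigenstructure makes the saturated reduction
  the practical assay model, mirroring how such assays are run.
* The β = 3 transition is a series/derivative criterion at the midpoint; it
  does not claim a thermodynamic phase transition (there is none in 1-D at
  finite couplings).
* Hill coefficients are protocol-dependent by nature; compare them only
  under the same protocol.
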