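# Methods

## Model

A dielectric instrument in the β-dispersion range reads a permittivity
increment ΔC (pF/cm) proportional to the concentration of membrane-intact
cells, offset by a residual background from killed broth:

    ΔC = β₁ X_viable + β₂ .

X_viable (g/kg) is not directly measurable; total cell dry weight (CDW)
includes dead cells and insoluble solids. The viability-control design makes
X_viable identifiable: mixing a fresh sample with its own heat-killed portion
at fresh mass fraction m gives

    X_viable = α_s · m · CDW_s ,

where α_s ∈ [0, 1] is the latent viable fraction of sample s's dry weight.
Heat-killing removes no solids, so the mixture's CDW equals the fresh
sample's — the mixing series varies viable biomass at constant total solids.
The calibration pools every point (fresh, mixed, fully killed) of every
series and maximizes the pooled R² over α subject to 0 ≤ α ≤ 1, with β₁ and
β₂ determined by least squares given α. R² is defined as 1 − SSE/SST with
SST about the grand mean of observed ΔC; replicate readings enter as
individual rows, unweighted.

### Identifiability and normalization

Predictions depend on α only through the products ρ_s = β₁ α_s, so (c·α,
β₁/c) is an exact symmetry: the α vector is identified only up to a common
positive scalar (a numerically asserted invariant in the test suite).
Reported solutions fix the scale by max(α) = 1 — the assumption that at
least one sampled broth is fully viable. The raw fitted ρ_s are retained on
the result (`alpha_raw`). Campaigns whose most-viable sample is well below
full viability will overestimate β₁ proportionally; this is a property of
the design, not of the solver.

### Solvers

*Closed form.* In (ρ, β₂) the model is linear: one regressor m·CDW_s per
sample plus a common intercept. Unconstrained least squares (`numpy.lstsq`)
gives the global SSE minimum; when a fitted ρ_s is negative (a pure-noise
series), the constrained optimum lies on the ρ_s = 0 boundary and is
obtained exactly by bounded least squares (`scipy.optimize.lsq_linear`,
ρ ≥ 0, intercept free). A rank check rejects designs where some series has
effectively one mixing level. ρ values below 1e−12 are treated as zero; if
none is positive the fit aborts with "no viable signal".

*Numerical.* `optimize_alpha` searches α ∈ [0, 1]^S by L-BFGS-B with β₁, β₂
profiled out by inner OLS (reducing the dimension to the number of samples),
started from the closed-form solution plus seeded random restarts
(default 8). Only candidate solutions whose profiled slope is positive are
admissible — a negative profiled slope describes no calibration, and the
oracle start always supplies an admissible candidate. Because such solutions
lie inside the closed form's feasible set, the optimizer can never exceed
the oracle's R²; it must reach it within tolerance (1e−10 on the objective)
or the fit reports non-convergence with the start-by-start trace. The
numerical route exists to demonstrate that the constrained-R² program is
well behaved for generic solvers; the closed form is the reference
implementation.

### Uncertainty

Standard errors come from a cluster bootstrap: whole mixing series are
resampled with replacement (points within a series share α, making the
series the exchangeable unit; default 200 replicates), and the closed-form
fit is recomputed per replicate. Because of the scale symmetry, each
replicate is first aligned to the full-data normalization — its α vector is
rescaled by the least-squares scalar matching it to the full-data α over the
drawn series, with β₁ rescaled inversely (predictions unchanged). Without
alignment, replicates that miss the most-viable sample would shift β₁ purely
through the max-α convention, yielding spurious variance even on noise-free
data (where the aligned SEs are exactly zero). α intervals are percentile
intervals of the aligned draws, clipped to [0, 1]. Replicates that cannot be
fitted are skipped and counted.

### Diagnostics and prediction

`per_sample_linearity` fits each series' ΔC against m by OLS; series with
zero ΔC variance report R² = 0 (not undefined) so reports stay total.
`cdw_correlation_diagnostics` computes the Pearson correlation of
fresh-point ΔC against total CDW per phase and overall (≥ 3 points per
group, smaller groups omitted with a warning). `predict_viable` inverts the
line, X = (ΔC − β₂)/β₁, clipping sub-background readings to 0 with a logged
warning.

## Container-volume transfer

Reading the same broth in a 2 mL tube attenuates ΔC relative to a 100 mL
container (wall effect). The two readings are related by a single scalar k,
estimated by through-origin least squares on paired fresh-sample readings:
k = Σxy/Σx², se(k) from the residual variance with one fitted parameter,
R² about the mean of the large-volume readings (the conservative, centered
convention). The through-origin estimator is the default because the pure
scalar model is the only one consistent with both the slope ratio and the
intercept ratio of independent calibrations at the two volumes (both ≈ 1.33
for the default instrument profiles); `slope_ratio_factor` exposes that
cross-check. No heteroscedasticity correction is applied. A per-sample
ratio mean would be a reasonable alternative estimator; it is not provided
as a separate method because on proportional data with small relative noise
the two agree to well within se(k).

## Synthetic campaign generator

The generator emulates a production-scale calibration study, since real
campaign data in this industry are confidential:

- **Design**: `n_samples` (default 26) over `n_cultivations` (default 21),
  phases assigned early/middle/decline in proportions 0.35/0.40/0.25, mixing
  levels {0, 0.25, 0.5, 0.75, 1} (must include 0 and 1), default total
  mixture mass 100 g.
- **Latent viability**: α drawn per phase — Uniform(0.85, 1) early,
  Uniform(0.6, 0.95) middle, Uniform(0.3, 0.8) decline; defaults are
  qualitative (no published α values exist to match) and every validation
  property is a recovery property, insensitive to the particular law.
  `force_full_viability` (default on) pins one sample's α at 1 so the max-α
  normalization coincides with the generator truth.
- **Precipitate**: decline-phase samples add insoluble solids of
  Uniform(0.1, 0.5) × biological dry weight to CDW without touching ΔC,
  reproducing the late-phase breakdown of CDW calibration. Ground truth
  keeps the balance CDW = viable + dead + precipitate with α defined against
  total CDW.
- **Noise**: ΔC noise is heteroscedastic Gaussian with sd = `noise_cv` × the
  noiseless ΔC (default 1 %); relative error matches instrument behaviour
  and keeps killed-point readings tight. Weighing error (default sd 0.05 g
  per dispensed portion, reflecting careful gravimetric work) perturbs the
  *achieved* fraction; the recorded masses are exact for the achieved
  mixture, so there is no errors-in-variables component — consistent with
  mixtures being accurately weighed after mixing.
- **Determinism**: one seed; per-sample sub-streams are spawned from it
  (`SeedSequence.spawn`) so enlarging a campaign leaves earlier samples'
  draws unchanged.

What the generator does **not** emulate: heat-kill kinetics (killed material
is simply background), instrument drift, morphology effects on the signal,
multi-frequency spectra (ΔC is scalar), or mechanistic growth dynamics. ΔC
and CDW magnitudes are free choices (default CDW 5–50 g/kg); no validation
property depends on them. Passing tests therefore show that the estimator
recovers the model's parameters under the model's own assumptions with
realistic noise — not that any particular real broth satisfies those
assumptions.

## Reference designs and problem sizes

`viacal.study_designs` pins the three validation conditions: the full-size
campaign (26 samples, 21 cultivations, α ~ Uniform(0.4, 1) with one sample
fully viable, CDW 5–50 g/kg, 1 % noise, seed 42), a 10-sample noiseless
campaign for exact recovery of the instrument constants (β₁ = 1.67,
β₂ = 9.49), and a 15-pair volume study (k = 1.33, 2 % noise, seed 7). These
sizes match the study design the package targets and keep every validation
run in seconds on one CPU. Default instrument profiles: viable-cell analyzer
(1.67, 9.49), annular probe 2 mL (0.89, 11.91), annular probe 100 mL
(1.18, 15.84), all in pF/cm per g/kg and pF/cm.

## Known limitations

- β₁ inherits the max-α normalization bias when no sampled broth is fully
  viable; the bootstrap quantifies sampling noise, not this design bias.
- The background β₂ is assumed common to all series of a campaign; broths
  whose killed-material background varies violate the model.
- The volume factor is treated as a property of the microbial system and
  container geometry; it must be re-estimated for a new organism or vessel.
- Bootstrap intervals for α of a rarely-resampled sample rest on few draws;
  `alpha_intervals.n_reps` reports how many.
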