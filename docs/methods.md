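# Methods

This note documents the models and procedures implemented in `scndev`,
the synthetic generative model used to validate them, the parameter
defaults and numerical choices, and the limitations of both.

## The pipeline

### Sliding-window construction

Scans are pooled across participants, sorted by age (ties broken by
scan id for determinism) and cut into windows of `bin_size` consecutive
scans placed at offsets 0, s, 2s, … while the window fits, where
`s = round_half_up(step_fraction × bin_size)`. When the last regular
window does not reach the end of the pool, one terminal window anchored
at the oldest `bin_size` scans is appended. This convention — sliding
over scans, with a terminal anchored window — yields 16 bins for
(80, 25%) and bin counts from 12 to 23 across the nine standard
configurations on a pool of 366 scans, and is locked by tests.

Windows are then deduplicated to one scan per participant: the window
median age is computed over all window scans, each participant keeps
the scan minimising |age − median| (ties to the lower scan id), and the
bin's median age is recomputed over the retained scans. Deduplication
may shrink a bin below `bin_size`; bins are not re-expanded.

### Residualization

Each region is regressed (OLS, across the full sample) on an intercept
plus sex, cohort and scanner; the values entering all networks are
internally studentized residuals, `e_i / (σ̂ √(1 − h_ii))` with
`σ̂² = RSS/(n − p)` and `h_ii` the leverage. Constant or aliased
covariates are dropped with a warning; a region fit perfectly returns
zeros. Note that studentized residuals are only *approximately*
mean-zero and orthogonal to the design (the leverage reweighting
perturbs both at the ~10⁻⁵ level at n ≈ 370); tests assert the
properties at a 10⁻³ tolerance.

### Bootstrap edge thresholding

Within a bin with n participants, B resamples of size n are drawn with
replacement; for every region pair the Monte-Carlo p-value of
"consistently positive" is `(#{b : r_b ≤ 0} + 1)/(B + 1)` (the add-one
convention keeps p > 0). Benjamini–Hochberg is applied across all
C(P, 2) pairs at level α; survivors with positive point-estimate
correlation become edges of a binary network. Degenerate (zero
variance) regions in a resample contribute r = 0, which counts as
non-positive. Diagnostics record the fraction of BH survivors whose
point estimate was negative.

### Graph metrics

Only density- and degree-based metrics are computed, because bootstrap
thresholding yields networks of varying density, which confounds
comparisons of higher-order metrics across bins. Standardized degree
uses the sample SD (n − 1); a regular graph returns all-zero z with a
warning rather than an error. Hubs require z > 1 (strict) in at least
2 bins. Modular densities (within-module edges / C(n_m, 2); between
edges / n_a·n_b) are normalized by the network's global density; a zero
global density or singleton module yields NaN, which downstream fits
skip.

### Trajectory model selection

A metric series (value vs bin median age) is fit by Gaussian maximum
likelihood with three nested mean models: constant, linear in age, and
a natural cubic spline of age with knots at the minimum, median and
maximum bin age — i.e. two basis functions beyond the intercept. This
is the unpenalized counterpart of a penalized smooth with basis
dimension 3: at that ceiling the penalized and unpenalized fits span
the same small space, and the unpenalized fit keeps the selection rule
exact. AIC is `−2 logLik + 2(p + 1)`, counting the ML error variance as
a parameter in every model so differences are internally consistent.
The more complex model is selected only when its AIC is at least 3
below *all* lower-order models. The smooth term's p-value is the
F-test of the two spline columns against the constant model; nodal and
modular batches are Benjamini–Hochberg corrected. Peak age is the
argmax of the fitted spline on a 501-point grid over the observed age
range (flagged when it falls on a boundary). Per-bin points are treated
as independent observations even though consecutive bins share scans —
a known property of the sliding-window design, inherited deliberately.

A "finding" is matched across window configurations as the modal
(selected model, direction-of-net-change) pair and reported only when
it occurs in strictly more than 50% of the nine configurations.

### Thinning rates and the surrogate map test

Per-region thinning rates are the age fixed effects of Gaussian linear
mixed models (fixed: sex, cohort, scanner, age; random: participant
intercept) fit by REML via statsmodels `MixedLM`; a region whose mixed
fit fails falls back to OLS and is flagged. Participants with a single
scan are handled naturally (the random-intercept variance simply
absorbs nothing).

The spatial null for map–map correlations is a simplified
variogram-matched surrogate scheme, generated per hemisphere: permute
the map, smooth it over the k nearest neighbours with inverse-distance
weights, rank-remap onto the source value multiset, and keep the k
(from a candidate grid, default {3, 5, 10, 20}) whose binned variogram
(10 equal-count distance bins) best matches the empirical map's. Every
surrogate therefore has exactly the source's value distribution, and
short-range variograms closer to the empirical map's than naive
permutations give (asserted by test). The non-parametric p is the
add-one proportion of surrogates whose correlation with the second map
reaches the empirical value — by default in absolute magnitude (the
planted association is negative); a signed one-sided option is recorded
in the result. Fidelity is asserted through variogram-matching and
calibration properties, not through equality with any external
implementation.

### Sex-stratified analysis

Within each sex the identical machinery runs on the stratum's own
age-sorted pool at the full bin size (a stratum smaller than the bin
size skips the configuration with a warning); residualization uses
cohort and scanner only. Global trajectories are compared between sexes
by a shared model (one spline of age plus a sex offset) against a
by-sex model (separate splines per sex, i.e. spline × sex interaction
columns), both Gaussian ML with a common variance; by-sex wins only at
ΔAIC ≥ 3. Modular densities are normalized by each stratum's own global
density and therefore reported descriptively, never tested across
sexes.

## The synthetic cohort generator

The generator emulates an accelerated longitudinal design of 192
participants contributing ~366 scans over ages 8.5–14.5: a "slow"
cohort (53%, up to 2 waves, gap 2.763 ± 0.243 y) and a "fast" cohort
(47%, up to 3 waves, gap 1.432 ± 0.222 y), with a scanner-upgrade flag
switching on at the fast cohort's third wave — exactly the confound
structure the residualization step must remove. Wave attendance is
sequential with a retention probability solved so the expected scan
total equals the target; draws are repeated (same seed stream) until
the realized total is within 5% of target. Baseline ages are uniform in
cohort-specific sub-ranges (8.5–10.7 and 9.5–11.4) so the pooled ages
span the range roughly uniformly; inter-wave gaps are truncated normal,
shrunk proportionally when a participant's last wave would overshoot
the age ceiling.

Thickness follows

    y(s, r, a) = μ_r + d_s + β_sex·sex + β_coh·cohort + β_scan·scanner
                 + slope_r (a − 8.5) + λ_r(a) f_{s,w} + ε,

with a global per-participant offset d_s ~ N(0, subject_sd²), noise
ε ~ N(0, noise_sd²), and an age-varying common-factor term: per scan
one global factor and one factor per module (all standard normal),
combined with weights 0.6/0.8 and loaded through
`λ_r(a) = loading_r · exp(−(a − peak)²/(2 width²))`. The Gaussian bump
concentrates shared variance around `peak` (default 11.5 y, width
1.1 y), producing the covariance peak; keeping it a single loading
curve keeps the generator low-dimensional and the peak location one
interpretable parameter. Regions in designated "hub" modules (1 and 2)
carry loadings boosted by 70%, so they hold more retained edges — and
hence higher standardized degree — wherever the factor signal is
present. Thinning slopes are drawn as
`slope_r = mean + sd (ρ ℓ_r + √(1−ρ²) η_r)` where ℓ_r is the
standardized loading and ρ = `thinning_degree_coupling` (default −0.7),
planting a negative thinning–degree association.

Default magnitudes (mm): baseline 2.7 with regional spread 0.15; sex /
cohort / scanner offsets 0.03 / 0.04 / 0.05; slopes −0.045 ± 0.015
mm/y (typical of adolescent cortical thinning); subject offset 0.03;
noise 0.12; peak loading 0.15 with ±20% regional jitter. These were
chosen together so that, at the validation scale (60 regions, bins of
70–90 scans, B = 200), off-peak correlations sit below the bootstrap
retention threshold while peak and hub structure clear it — i.e. the
planted structure is identifiable, not trivially saturated.

The sex effect is a constant offset by default, so the sex-stratified
machinery has a testable null; `peak_age_by_sex` optionally plants
different bump centres per sex.

### What the generator does not emulate

No spatial noise correlations beyond the module factors, no
heteroscedasticity across regions, no distance-dependent covariance
decay, no measurement floor/ceiling, no missing data, no non-Gaussian
tails, and linear-only true thinning. Passing tests therefore show the
pipeline recovers structure of this kind at these signal-to-noise
levels; they do not certify behaviour under realistic artefacts such as
motion or segmentation error.

### Emergent coupling and the sharp null

One finding from building the generator is worth stating explicitly:
setting the coupling parameter to zero does **not** make the
thinning–degree association test null. Two emergent channels remain.
First, age is deliberately *not* residualized out of the networks, so
inside wide late-age bins heterogeneous thinning rates act as a common
factor: steeper-thinning regions genuinely covary more and acquire
higher degree (correlation of true slope with oldest-bin degree around
−0.55 under defaults even at zero coupling). Second, the slope map and
the degree map are estimated from the same scans, so common-factor
realizations push mixed-model slope errors in the direction of
loading-driven degree. Both are properties of the method, not bugs; the
same caveat applies to real cohorts, where the slope and network maps
share the data. The package therefore exposes
`synthetic.null_coupling_config()` — homogeneous thinning rates, no
factor loadings, and a slightly larger subject offset (0.07) so
baseline correlations keep the thresholded network non-degenerate — as
the sharp "nothing planted" null; under it the oldest-bin test rejects
at ≈5% as it should.

## Problem sizes used in validation

The validation suite scales simulations to run quickly on one CPU:
bootstrap B = 200 (recovery) or 100 (replicated nulls) instead of the
analysis default 1000; 200 surrogates for single recovery tests and 100
for replicated calibrations instead of 1000; the sharp-null calibration
uses 100 replicates of a 24-region, 100-participant cohort with a
single window configuration; the surrogate calibration uses 500
replicates of 30-region maps. Monte-Carlo tolerances follow these
sizes (e.g. retention and type-I rates bounded at 5%, calibration rate
within [0.02, 0.09]). All stochastic tests run under fixed seeds;
end-to-end runs derive every stage seed from the root seed plus a
stage/configuration/bin tag, so results are reproducible bit-for-bit.

## Numerical choices

- Bootstrap p-values and surrogate p-values use the add-one convention;
  p is never exactly 0.
- Step sizes round half-up (70 × 0.25 → 18); the printed bin-count
  extremes are invariant to this choice.
- Zero-variance guards: degenerate regions yield r = 0 (flagged), a
  constant-degree network yields z = 0 ("no hubs"), a constant map
  yields surrogates equal to the map, and a degenerate map in the
  association test returns a flagged null result instead of NaN
  propagation.
- Perfect covariate fits (σ̂ ≈ 0 relative to the region's scale) return
  zero residuals.
- Spline knots at min/median/max of bin median ages; if the median
  coincides with an extreme (fewer than 3 distinct ages), the smooth
  model is unavailable and recorded as +∞ AIC.
- Mixed-model non-convergence falls back to OLS with a per-region flag
  so batch runs always complete.

## Limitations

- Consecutive bins share scans; trajectory fits treat them as
  independent. Confidence statements about trajectories are therefore
  optimistic; model *selection* with the ΔAIC ≥ 3 margin is the
  intended safeguard.
- The surrogate scheme is a simplified variogram-matched generator; it
  preserves the value multiset exactly and the variogram approximately,
  but is not guaranteed to match any particular published
  implementation's draws.
- The oldest-bin association test inherits the estimation-dependence
  caveat described above: a significant result can reflect shared
  estimation structure as well as planted coupling.
- The windowing convention (sliding over scans, terminal anchored
  window) is one of several consistent with "equal sample size +
  incremental step"; it is the one that reproduces the reference bin
  counts and is locked by tests.
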