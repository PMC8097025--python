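# scndev — development of structural covariance networks

`scndev` analyses how **structural covariance networks** (SCNs) change
across late childhood and early adolescence. An SCN is a graph whose
edges are across-participant correlations of regional cortical
thickness: regions that thicken and thin together are connected. The
package implements a sliding-window pipeline for accelerated
longitudinal cohorts (here, ages 8.5–14.5 years), together with a
synthetic-cohort generator that plants known structure so every stage
can be validated without access to restricted imaging data.

It is intended for researchers analysing parcellated morphometry tables
(one thickness value per region per scan) who want robust, binarized
covariance networks and model-selected developmental trajectories.

## Method

1. **Sliding age-windows.** Scans are pooled, sorted by age and cut
   into overlapping bins of fixed size *n* ∈ {70, 80, 90} advanced by a
   step of {20, 25, 30}% of *n* (nine configurations). Within a window
   each participant contributes only the scan closest to the window's
   median age. Each bin is indexed by the median age of its retained
   scans.
2. **Networks.** Thickness is residualized region-wise on sex, cohort
   and scanner (internally studentized residuals); each bin's network
   is the region × region Pearson correlation matrix.
3. **Bootstrap thresholding.** Within each bin, participants are
   resampled with replacement *B* = 1000 times; an edge survives only
   if its correlation is consistently positive across bootstraps
   (add-one Monte-Carlo p, Benjamini–Hochberg FDR at α = 0.05 over all
   region pairs). Surviving edges are binarized.
4. **Graph metrics.** Global density, nodal degree and standardized
   degree *z* = (k − mean k)/SD k; hubs are regions with *z* > 1 in at
   least two bins; intra-/inter-modular densities over a 7-way module
   assignment, normalized by global density.
5. **Trajectories.** Each metric's per-bin series is fit against median
   age with three Gaussian ML models — null (∼1), linear (∼age) and
   smooth (natural cubic spline of age, knots at min/median/max; the
   k = 3 basis ceiling) — and the more complex model is selected only
   when its AIC is ≥ 3 below every lower-order model. Findings must
   recur in > 50% of the nine window configurations to be reported.
6. **Thinning–degree association.** Per-region thinning rates β_age
   come from random-intercept linear mixed models
   (thickness ∼ sex + cohort + scanner + age, participant intercept,
   REML). Their correlation with standardized degree in the oldest bin
   is tested per hemisphere against 1000 variogram-matched surrogate
   maps that preserve the thinning map's value distribution and spatial
   autocorrelation.
7. **Sex-stratified runs.** The pipeline re-runs inside each sex
   (residualizing on cohort and scanner only) and compares global
   trajectories with a shared-smooth vs by-sex-smooth model under the
   same ΔAIC ≥ 3 rule.

## Worked example

```python
import pandas as pd
from scndev import (SyntheticConfig, generate_parcellation, generate_dataset,
                    residualize, build_bins, WindowConfig, bootstrap_threshold,
                    BootstrapSpec, global_density, standardized_degree,
                    fit_trajectory, fit_thinning_rates,
                    thinning_degree_association, SurrogateSpec)

parc = generate_parcellation(n_regions=60, n_modules=7, seed=7)
table, truth = generate_dataset(SyntheticConfig(seed=11), parc)

resid = residualize(table)
bins = build_bins(resid, WindowConfig(bin_size=80, step_fraction=0.25))
nets = [bootstrap_threshold(resid, b, BootstrapSpec(B=200, seed=100 + b.index))
        for b in bins]

dens = [global_density(n.retained) for n in nets]
fit = fit_trajectory([b.median_age for b in bins], dens,
                     metric_id="global_density")

rates = fit_thinning_rates(table)
z = pd.Series(standardized_degree(nets[-1].retained), index=nets[-1].region_ids)
res = thinning_degree_association(rates, z, parc, SurrogateSpec(n_surr=200, seed=41))
```

Output (printed by the snippet with a few `print` statements):

```
scans: 374, participants: 192
age-bins: 16, median ages 9.32-13.10
selected model: smooth, peak age: 11.58 (planted 11.5)
L: r = -0.665, surrogate p = 0.0050
R: r = -0.682, surrogate p = 0.0100
```

The generator planted an inverted-U in global covariance peaking at age
11.5 and a negative coupling between regional thinning rates and
late-age degree. The pipeline selects the nonlinear ("smooth") density
trajectory with its maximum at 11.58 years, and finds that
faster-thinning regions have higher standardized degree in the oldest
bin (negative r, significant against the spatial surrogate null in both
hemispheres).

The same run end-to-end from a shell:

```sh
scndev run-all --seed 11 --out scn_out/
```

writes scan tables, bin manifests, metrics, trajectory fits, the
consensus report, thinning associations, sex-stratified densities and a
`manifest.json` with content hashes (reruns with the same seed are
byte-identical).

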