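# Methods

## The morphometric MVD statistic

Microvessel density is quantified as an area fraction: the percentage
of chromogen-positive *clustered* pixels over all analysed tumour
tissue pixels. The analysis area is the union of the tumour-delineation
polygons minus the union of the damage/exclusion polygons, rasterized
with a pixel-centre point-in-polygon test (a pixel at row r, column c
counts as inside if its centre (c + 0.5, r + 0.5) lies in the even-odd
filled union; simple polygons are assumed, self-touching rings are
repaired). The physical pixel size (default 0.23 µm, a typical 20×
whole-slide scan) is carried as metadata but does not enter the
statistic, which is dimensionless.

Positive-pixel classification defaults to an RGB rule with three
conjunctive thresholds, `R >= 100`, `R − B >= 60`, `R − G >= 20`. The
original workflow's exact RGB constants live in supplementary material
we do not reproduce; our defaults were calibrated once on the synthetic
renderer (below) so that DAB-brown vessel pixels sit several noise
standard deviations inside the rule and the hematoxylin/eosin-like
backgrounds several outside, and all three thresholds are configuration
parameters so that any laboratory's constants can be dropped in. An
alternative mode projects optical density (−log10((I+1)/256) per
channel) onto a unit DAB stain vector (Ruifrok-Johnston direction
(0.268, 0.570, 0.776)) and thresholds at 0.15 OD.

Clusters are maximal connected components of the positive mask,
8-connected by default (the common particle-analysis convention;
4-connectivity is a flag). The microvessel size threshold retains
components of at least `min_pixels` (default 100, read inclusively:
a 100-px component stays, a 99-px one is removed entirely). Removed
pixels leave the numerator but stay in the denominator — the
denominator is always the full analysed tissue area. Slides at the
sizes in scope label in a single pass; no tiling is needed, which makes
the result trivially independent of any tile decomposition.

Degenerate inputs: an empty analysis mask raises ("no analysable
tissue"); an all-negative classification is a valid 0% result; the
statistic is bounded in [0, 100] by construction.

## Point-grid stereology for TSP

A square lattice with spacing `s = sqrt(mask_area / n_points)` and a
uniformly random offset in [0, s)² is intersected with the analysis
mask; nodes outside the mask are discarded rather than redrawn, so the
*expected* in-mask count equals `n_points` (400 by default) and the
hit fractions are unbiased estimators of area fractions — the random
offset makes this property literal, and a fixed-origin mode exists for
reproducing a specific count. Masks smaller than `n_points` pixels are
rejected.

Each point is scored epithelium / stroma / other, either automatically
from a class-map raster (the synthetic ground truth, or any supplied
segmentation) or from a manually scored table, one row per point, which
preserves the original operator-scored workflow. TSP is
`100 · stroma / (stroma + epithelium)`; "other" hits (lumen, mucus,
vessels, background) are excluded from both numerator and denominator,
which is our reading of the hits formula; zero informative hits is an
error rather than a silent 0/0.

## Marker dichotomization

Continuous markers are dichotomized per disease stage (mirroring the
separate stage II and III cutoffs of the study design): every midpoint
between consecutive sorted distinct values is evaluated in both
directions, and the cutoff maximizing Youden's J = sensitivity +
specificity − 1 is selected, ties broken toward the smallest cutoff and
the high-positive direction. The "high" group is strictly greater than
the cutoff. The outcome against which the ROC is computed defaults to
the disease-recurrence indicator (`dfs_event`) and is a parameter — the
original report does not state its choice, and we make no claim about
it.

## Survival analysis

Disease-free survival is time from surgery to recurrence; death
without recurrence is treated as censoring by default (the composite is
parameterizable, as the source design leaves it open). Kaplan-Meier
curves use the product-limit estimator; at tied times, events precede
censorings in the risk set. Group comparison uses the two-sided
log-rank test. Hazard ratios come from Cox partial-likelihood fits
(statsmodels PHReg) with Breslow tie handling by default — consistent
with SPSS, the package used in the original analysis — and Efron by
flag; 95% CIs are Wald intervals exp(β ± 1.96·SE). Non-convergence and
monotone likelihoods (|β| > 20 or SE > 100, i.e. perfect separation)
raise an explicit `ConvergenceError`.

The multivariate model uses backward stepwise elimination: fit all
candidates, remove the single covariate with the largest Wald p
exceeding p-out = 0.1, refit, repeat; no re-entry; an empty final model
is a valid outcome and the full removal trace is recorded. Subjects
with follow-up beyond 60 months are administratively censored at the
horizon first (5-year DFS). If the full model is not estimable, a
drop-one retry removes the first covariate whose exclusion restores
estimability (recorded with p = NaN) before giving up. Candidate
markers enter as their per-stage high/low indicators; grade enters as
poor-vs-rest. Missing marker values are handled by listwise deletion
within each analysis. All tests are two-sided at 0.05 with no
multiplicity adjustment, matching the source design.

Baseline tables report counts (%) per group with the uncorrected
Pearson chi-square — the uncorrected form reproduces the published
per-row p-values exactly (e.g. recurrence counts [[11,4],[14,25]] give
p = 0.013), whereas Yates-corrected values do not — and mean (sd) with
the pooled-variance t-test for continuous rows. Normality checks use
the Kolmogorov-Smirnov test with the Lilliefors correction, since the
normal parameters are estimated from the sample. Mann-Whitney U uses
the exact distribution for small untied samples and the tie-corrected
normal approximation otherwise. Spearman's rho uses midranks with the
two-sided t approximation.

## The synthetic slide generator

The generator emulates a delineated CD31-stained section: a tissue
polygon (default: the frame inset by 2%) on a near-white background,
an epithelium/stroma partition drawn by thresholding a
Gaussian-smoothed random field at the requested stroma quantile
(default 40% stroma), and vessel objects — ellipses and lumen-bearing
annuli with sinusoidally jittered boundaries, 40% annuli, aspect ratios
0.5–1 — placed uniformly inside tissue with at least one background
pixel between objects so each vessel stays its own 8-connected
component. Colours: DAB-brown vessels (150, 90, 40),
hematoxylin-purple epithelium (150, 120, 190), eosin-pink stroma
(235, 195, 215), near-white lumen (245, 245, 245), each perturbed by
per-channel Gaussian noise (default SD 8, clipped to [0, 255]). At
these settings the brown rule's per-pixel error rate is ~2·10⁻⁴, so
classification noise contributes ~0.01 percentage points to the MVD
estimate.

Vessel areas are drawn uniformly from the configured size range and
then scaled so their sum matches the target positive-pixel count; the
range acts as a prior on the relative size mix rather than a hard bound
on the scaled areas, and clearly impossible configurations (a positive
target with zero vessels, targets above the 35% non-contact packing
limit, mean areas beyond 50× the configured maximum) are rejected at
construction. The last vessel is a plain disk whose area is found by
bisection so the realized fraction lands on the target (well within the
0.5 percentage-point contract; in practice ~0.01 pp). All truth
quantities — positive fraction, per-vessel pixel counts, stroma
fraction — are recomputed from the emitted arrays, never taken from the
nominal parameters, so "truth equals brute-force recount" holds
exactly. Damaged/excluded regions are stamped as random disks until the
requested tissue fraction is covered, and truth is recomputed over the
reduced denominator.

What the renderer does *not* emulate: nuclei-level texture, stain
gradients, scanner artefacts, out-of-focus regions, or genuinely
ambiguous vessel boundaries. Passing recovery tests therefore
demonstrate that the measurement chain is exact given a correct colour
rule, not that the default rule is optimal for any particular scanner
or staining protocol — on real material the rule's constants must be
calibrated, which is why they are configuration, not constants.

## The cohort simulator

Cohorts have configurable stage II / III sizes (defaults 53/54, the
published series), binary covariates at configurable prevalences
(defaults near the published margins: male 0.62, right-sided 0.40,
ulceration 0.80, angioinvasion 0.25, mucinous 0.16), stage-specific age
distributions, and log-normal marker distributions with stage medians
5.6% and 11.1% (the published stage II/III MVD medians) and sigma
0.6/0.5. TMA-style scores are built from six ordinal (0–3) cores around
a latent level with 5% missing cores, aggregated by the mean of
non-missing cores.

Survival is exponential proportional hazards: subject hazard
`h0 · exp(Σ β_j x_j)` per month with baseline `h0 = 0.007` (≈34% events
by 60 months at null covariates). Effects can attach to any generated
column, to the marker's true high/low split (`mvd_high`, cut at the
known distribution median), or stage-restricted (`mvd_high:III`).
Censoring is an independent exponential whose rate c solves
`mean(c / (c + h_i)) = censor_rate` (Brent root-finding), plus an
administrative cutoff (default 120 months); the realized censored
fraction equals the target when the cutoff is far beyond the event
horizon. The exponential baseline keeps the inversion closed-form; a
Weibull baseline was deliberately not added since no validated property
requires shape flexibility.

This simulator reproduces the *structure* of a two-stage cohort, not
the joint dependence of real clinicopathological covariates (they are
drawn independently), so stepwise-selection results on synthetic data
speak to algorithmic correctness, not to confounding behaviour on real
cohorts.

## Problem sizes and numerical choices

Validation runs use 2000×2000 px slides (the scale of the smaller
published scans) for the morphometry recovery panel and 600–800 px
slides elsewhere; cohort simulations use n = 300–400 with 200
replicates for estimator calibration and 50 replicates for the
stage-effect pattern. Coordinates are 0-based; the grid offset, vessel
placement and all cohort draws flow from a single NumPy Generator per
seed, so every artifact is bit-reproducible given its spec. Tolerances:
slide target fraction within 0.5 pp (achieved ~0.01 pp); chi-square
p-values are exact; Youden cutoffs match an exhaustive scan exactly;
Cox calibration is judged by Monte-Carlo standard error and 95% CI
coverage.

## Known limitations

- The RGB rule is conjunctive and global; it has no spatial smoothing
  and will misclassify chromogen-like pigments (haemosiderin) on real
  tissue.
- Hot-spot analyses, vessel counts per mm², and automated
  epithelium/stroma segmentation from raw H&E colour are out of scope
  by design.
- The stepwise procedure inherits the usual instability of p-value
  based selection; the removal trace is recorded so selections can be
  audited.
- Whole-slide pyramid formats are not read; inputs are plain TIFF/PNG
  rasters.
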