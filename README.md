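# mvdquant

Digital morphometry of microvessel density (MVD) from CD31-stained
whole tumour sections, point-grid stereology of tumour-stroma
percentage (TSP), and the cohort statistics that turn those markers
into prognostic results — plus synthetic-data simulators that make the
whole chain testable against pixel-exact and model-exact ground truth.

It is written for researchers in digital pathology and clinical
biostatistics who want a reproducible, observer-independent version of
this analysis chain, or a controlled bench to validate their own.

## What it computes

**MVD as a positive-area fraction.** Within the delineated tumour area
(include polygons minus damaged/excluded regions), chromogen-positive
(DAB-brown) pixels are classified by an RGB rule
(`R >= r_min`, `R - B >= d_rb`, `R - G >= d_rg`; a stain-deconvolution
mode is also available), clustered by 8-connected component labeling,
and components below a minimum microvessel size (default 100 px) are
discarded. The statistic is

    MVD% = 100 · (positive pixels in retained clusters) / (analysed tissue pixels)

— an area fraction over the whole annotated tumour, deliberately not a
hot-spot vessel count per mm².

**TSP by point counting.** A systematic square lattice of ~400 points
with a random sub-cell offset is laid over the analysis mask; each
point is scored epithelium / stroma / other, and

    TSP% = 100 · stromal hits / (stromal + epithelial hits).

**Cohort statistics.** Continuous markers are dichotomized per disease
stage at the Youden-optimal ROC cutoff (J = sensitivity + specificity − 1,
"high" = strictly above the cutoff); groups are compared with
uncorrected Pearson chi-square and pooled-variance t-tests
(Mann-Whitney U and Lilliefors-corrected Kolmogorov-Smirnov included);
disease-free survival is analysed with Kaplan-Meier curves, log-rank
tests, Cox proportional-hazards models (HR = exp(β), 95% CI =
exp(β ± 1.96·SE), Breslow ties) and backward-stepwise elimination at a
Wald p-out of 0.1 with administrative censoring at 60 months;
associations use Spearman's rho.

**Synthetic ground truth.** Because the original patient data are not
publicly deposited, the `synthetic` module generates (a) slide images
with brown vessel objects of a controlled total area fraction on
tissue-coloured backgrounds, with pixel-exact masks, and (b) two-stage
cohorts with configurable covariate prevalences and exponential
proportional-hazards survival with known log hazard ratios and tuned
censoring. Every downstream estimate is validated against these truths.

## Worked example

```bash
mvdquant simulate-slide --width 800 --height 800 --target-fraction 0.05 \
    --vessels 20 --seed 7 --out slide7
mvdquant mvd --image slide7/image.tif --mask slide7/tissue_mask.png --out mvd7.json
mvdquant tsp --mask slide7/tissue_mask.png --class-map slide7/class_map.png \
    --seed 1 --out tsp7.json
mvdquant stats --table2x2 11,4,14,25
```

prints

```
slide written to slide7 (true positive fraction 0.0500)
MVD = 5.003% (20 components, 589824 analysed px)
TSP = 40.47% (155 stroma / 228 epithelium hits)
chi2 = 6.1064, df = 1, p = 0.01347
```

The generated slide carries a true vessel-area fraction of exactly
5.00%; the morphometry recovers 5.003% from the rendered image alone.
The TSP estimate counts 155 stromal of 383 informative hits on a
400-point grid (this slide's true stroma share is 40.7%). The last line
is the uncorrected chi-square for a 2×2 table of recurrence counts by
marker group — the kind of comparison a baseline cohort table is built
from.

The numbered scripts under `analysis/` run the same stages as a
narrative: simulate a slide panel, quantify MVD against truth, estimate
TSP, simulate study-sized cohorts with a harmful high-MVD effect in
stage II and a protective one in stage III, run the survival layer, and
measure how often the opposite-direction pattern is recovered. Each
writes its tables under `results/`.

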