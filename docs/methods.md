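# Methods

This note documents the models, conventions and numerical choices behind
`tmacyto`, and what the synthetic validation does and does not demonstrate.

## Data model and conventions

A cell table has one row per segmented cell: `sample_id`, `cell_id`,
coordinates `x_um`/`y_um` (µm, origin at the core bounding-box lower-left,
y increasing upward), and one intensity (arbitrary fluorescence units) per
marker. One intensity per marker per cell is assumed to be the *mean* over
the marker's compartment — nuclear for DAPI and FOXP3, cytoplasmic for CD3,
CD8, CD68, PD-1, PD-L1 and the tumor marker (PanCK/SOX10). Segmentation
platforms often export pixel-based, y-down coordinates; the reader's
`pixel_size_um` and `flip_y` options convert on ingest. Metadata carries one
row per sample (`tissue_class` ∈ {tumor, adjacent_normal, negative_control},
core diameter, optional tissue area, and survival covariates for patient
samples).

## Gating

Thresholds are the empirical quantile (numpy's linear / type-7 interpolation)
of the negative-control intensities, one threshold per marker for the whole
cohort; default quantile 0.99. The control slide omits antibody stains but
keeps the nuclear counterstain, so its DAPI signal is positive: the DAPI gate
therefore uses the *lower*-tail quantile (1 − q) so that real nuclei pass,
while every antibody marker uses the upper-tail quantile of its unstained
noise. Positivity is strict (`intensity > threshold`), which makes the
constant-control corner case well defined. Whether a single cohort-wide
threshold or per-slide thresholds are appropriate depends on acquisition
batch structure; the per-cohort choice is recorded in the ThresholdSet
provenance and a per-slide variant amounts to calling `estimate_thresholds`
per control slide.

The phenotype hierarchy is an ordered first-match rule list
(`DEFAULT_GATING_RULES`), mirroring sequential flow-cytometry gating:
tumor-marker⁺ outranks immune markers (PD-L1_Tumor when also PD-L1⁺); within
tumor-marker⁻ cells the CD3 branch outranks CD68 (a CD3⁺CD68⁺ vector is a
T cell); within CD3⁺, CD8 outranks FOXP3, and PD-1 refines CD8⁺ cells into
exhausted cytotoxic T cells; CD68⁺ cells split on PD-L1; everything else is
Other. PD-1 on non-CD8 cells and PD-L1 on T cells remain in the positivity
vectors but create no label. DAPI⁻ events are dropped (counted in the log)
before assignment, so the labels partition the DAPI⁺ cells exactly.
Alternative hierarchies are a matter of editing the rule list.

The 99th-percentile rule implies ≈1% false-positive calls per marker among
truly negative cells *by construction* (slightly above 1% in expectation:
the type-7 0.99-quantile of an n-sample has expected exceedance
(n−k+1)/(n+1) ≈ 1.05% at n = 2000, with sampling sd ≈ 0.22%). With the
default 20× positive/negative separation, false negatives are negligible
(≈10⁻⁴), so per-marker accuracy sits at ≈99% and hierarchical label accuracy
at ≈98%; these are properties of the thresholding convention, not defects of
the implementation.

## Quantification

Densities divide phenotype (and marker-combination) counts by the tissue
area in mm². When metadata supplies no area it is computed from the convex
hull of the sample's cells; the nominal disc area π(d/2)² is available as an
alternative (`area_method="disc"`). Whole-core area is the default
denominator — no tumor/stroma segmentation is attempted. Subset proportions
use marker-combination counts (e.g. p(CD8⁺|CD3⁺) = |CD3⁺CD8⁺|/|CD3⁺|);
zero-denominator proportions are NaN, flagged, and excluded from group
statistics rather than zero-filled, to avoid artificial zeros in sparse
cores. Group comparisons default to the classic equal-variance two-tailed
Student t (Welch by flag); no multiple-testing correction is applied across
panels — raw p-values are reported and logged. Cross-method density
correlation reports Pearson r with the least-squares line and a t-based 95%
CI of the slope.

## Spatial proximity

The band statistic assigns each query cell once, to the band of its
nearest-reference distance: ten equal-width half-open bands [0,10), …,
[90,100) µm by default (a distance of exactly 100 µm falls outside).
Percentages are 100 × band count / total query cells in the sample, so a
profile sums to ≤ 100. Platform proximity tools sometimes count *all*
query–reference pairs per band instead; that variant is available as
`metric="pairwise"` (normalised by |Q|·|R|), but the nearest-neighbour form
is the default because it keeps percentages bounded and reads directly as
"fraction of T cells within d of a macrophage". Nearest-neighbour queries use
a k-d tree and are tested for exact equality against an O(n²) scan.
Cross-sample comparison of two query phenotypes is an unweighted per-band
t-test over per-sample percentages (samples, not cells, are the replication
unit); bands with fewer than two defined values per group are skipped and
logged. Ripley's K, pair-correlation functions and permutation-based
neighbourhood enrichment are out of scope.

## Survival

Median splits use the strictly-greater-than rule (ties at the median → low);
undefined statistics exclude the patient with a log entry. The four-group
cluster is the cross of the p(PD-1⁺CD8⁺|CD8⁺) and p(PD-L1⁺CD68⁺|CD68⁺)
splits. Kaplan–Meier, log-rank (k-group via the multivariate form) and Cox
fits are delegated to lifelines; Cox uses Efron tie handling and Wald 95%
CIs, warns below 10 events, and rejects constant covariates. The "cluster"
covariate entering the Cox model and ROC is the binary high/high-vs-rest
indicator by default (`cluster_encoding="four_level"` gives the ordinal
4-level variant). The 1-year ROC dichotomises outcome at 12 months and
*excludes* patients censored before 12 months (logged); a time-dependent ROC
is deliberately out of scope. Stage enters the Cox model ordinally (1–4);
stage-stratified analyses dichotomise at 1–2 vs 3–4.

## Synthetic cohort generator

The generator is the package's validation instrument; its defaults are fixed
study conditions, not tuning knobs.

* **Geometry.** Circular cores, diameter 1.5 mm; counts per phenotype are
  Poisson(density × area); positions are uniform on the disc (exact, by
  radial inversion).
* **Composition (cells/mm²).** Tumor cores: tumor 400, CD3⁺CD8⁻ T 45,
  CD3⁺CD8⁺ 40, Treg 18, CD68⁺ 80, other 150 — giving a CD8 share of the
  T-cell compartment of 38.8%, matching the ~39% reported for tumor tissue
  in this disease setting. Adjacent-normal cores: epithelium 300 (the tumor
  marker also stains normal epithelium), CD3⁺CD8⁻ 50, CD3⁺CD8⁺ 75, Treg 10,
  CD68⁺ 70, other 150 (CD8 share 55.6%, matching ~55%). These are
  qualitative targets for realism, not estimates from any dataset.
* **Intensities.** Two-component log-normal mixtures per marker (fluorescence
  is right-skewed): negative log-mean 2.0, positive log-mean 2.0 + ln 20
  (20× separation), log-sd 0.5 for both. The negative control draws every
  antibody marker from the negative component and DAPI from the positive one.
  No spectral spillover or autofluorescence gradients are modelled.
* **Functional fractions.** Per patient, logit(p(PD-1⁺|CD8⁺)) and
  logit(p(PD-L1⁺|CD68⁺)) are bivariate normal with means logit(0.35), sds
  0.8 and correlation ρ = 0.8; adjacent-normal cores apply a −1.2 logit
  offset (checkpoint expression is lower outside the tumor). PD-L1⁺ tumor
  fraction 0.30 (tumor) / 0.10 (normal).
* **Attraction.** A Thomas-like parent–offspring displacement rather than a
  Gibbs interaction model — constructive, cheap, and sufficient to plant a
  near-band contrast: each PD-1⁺CD8⁺ cell is, with probability κ/(1+κ),
  re-placed at a N(0, σ²I) offset (σ = 15 µm) from a uniformly chosen
  PD-L1⁺CD68⁺ macrophage, rejection-resampled into the disc. κ = 0 yields
  complete spatial randomness (verified via Clark–Evans against matched
  uniform draws); the pdac-like preset uses κ = 3. If a core happens to draw
  no reference cells the affected cells stay uniform (a parameter-level error
  is raised only when the composition makes references impossible).
* **Survival.** Exponential proportional hazards so Cox fits are correctly
  specified: baseline 0.035 events/month at the reference covariates
  (proportions 0.35, age 63, stage 2), log-hazard coefficients 1.6 and 1.0
  on the two true proportions, 0.02/year on age, 0.1 on male sex, 0.35 per
  stage; independent exponential censoring at 0.03/month plus administrative
  cut-off at 72 months (≈45% censoring). Median survival is ~20 months at
  reference covariates, typical for resected PDAC cohorts.
* **Cohort shape.** Default 84 patients with paired adjacent-normal cores for
  a 73/84 fraction, plus one 2,000-cell negative-control slide. Randomness
  flows through a single SeedSequence with per-sample substreams, so cohorts
  are bit-reproducible and adding a sample leaves the others unchanged.

What passing the synthetic checks shows: the estimators recover what the
generator plants, at realistic sample sizes, with correctly calibrated error
rates (log-rank type-I ≈ 0.05; Cox CI coverage ≈ 0.95; per-band false
positives ≈ 0.05 under κ = 0). What it does not show: robustness to
segmentation error, spectral spillover, intensity batch effects, tissue
folds, non-circular or partially detached cores, non-proportional hazards,
or informative censoring — none of which the generator emulates.

## Problem sizes

Validation uses 20 cores for gating recovery, 1,000 synthetic cohorts
(n = 84) for log-rank calibration, 200 replicates (n = 300) for Cox
recovery, 100 replicate cohorts for the proportion-correlation check and
50 each for the attraction and null proximity checks; the spatial
nearest-neighbour path is checked for exact oracle equality on 50 random
configurations of up to 300 × 300 points. These sizes put Monte-Carlo
standard errors well inside the asserted bounds while keeping a full
validation run to a few minutes on one CPU.

## Known limitations

* Gating is threshold-based by design; mixture-model auto-gating and
  per-core adaptive thresholds are out of scope.
* The intensity mixtures are homogeneous across markers; real panels differ
  per fluorophore. The mixture parameters are free choices exposed in the
  model objects, not estimates.
* Whether platform band percentages are per-reference-cell averages or
  query-cell fractions is ambiguous in the wild; both are implemented and
  the default is documented above.
* The 1-year ROC exclusion rule discards early-censored patients and can
  bias AUC when early censoring is informative.
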