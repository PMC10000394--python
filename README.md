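# tmacyto

Image-cytometry analysis of multiplex immunohistochemistry (mIHC) tissue
microarrays, starting from per-cell segmentation exports. The package is for
researchers who quantify the tumor immune microenvironment from 8-plex panels
(DAPI, CD3, CD8, FOXP3, CD68, PD-1, PD-L1, PanCK/SOX10) and ask whether
functional T-cell/macrophage subsets — rather than raw cell densities — carry
prognostic information.

## What it computes

Given a per-cell table (coordinates in µm, one intensity per marker) and
per-sample metadata, the pipeline performs:

1. **Threshold gating.** Per-marker cutoffs at an empirical quantile
   (default q = 0.99, type-7 interpolation) of a negative-control slide's
   intensities; a cell is positive when intensity > threshold. Hierarchical
   rules then assign one phenotype per DAPI⁺ cell (Tumor ≻ CD3 branch ≻ CD68
   branch ≻ Other; CD8 ≻ FOXP3 within CD3⁺), including the functional labels
   CD3⁺CD8⁺PD-1⁺ (exhausted cytotoxic T) and CD68⁺PD-L1⁺ (immunosuppressive
   macrophage).
2. **Quantification.** Densities (counts / tissue area), subset proportions
   such as p(CD8⁺|CD3⁺) and p(PD-1⁺CD8⁺|CD8⁺), CD68/CD3 and FOXP3/CD8 ratios,
   two-group Student t comparisons, and Pearson/least-squares cross-method
   correlation of densities.
3. **Spatial proximity.** For query phenotype Q and reference phenotype R,
   each Q cell is binned by the Euclidean distance to its nearest R cell into
   ten half-open 10 µm bands covering [0, 100) µm; band percentages
   (100 × band count / |Q|) are compared across samples between two query
   phenotypes by per-band t-tests.
4. **Survival.** Median-cutoff high/low stratification (ties → low),
   Kaplan–Meier product-limit curves, (k-group) log-rank tests, a four-group
   cluster from the cross of two median splits, 1-year ROC/AUC, and a
   multivariate Cox proportional-hazards model
   λ(t|z) = λ₀(t)·exp(βᵀz) over cluster, age, sex and stage (Efron ties;
   Wald 95% CIs; forest-plot table).

Because cohorts of this kind are rarely public, the package ships a
first-class **synthetic cohort generator**: Poisson phenotype counts on a
1.5 mm disc, log-normal positive/negative intensity mixtures, a Thomas-like
attraction process placing a κ/(1+κ) fraction of PD-1⁺CD8⁺ cells at Gaussian
offsets (σ = 15 µm) from PD-L1⁺CD68⁺ macrophages, per-patient functional
fractions drawn from a logit-scale bivariate normal (ρ = 0.8), and censored
exponential proportional-hazards survival driven by the true fractions. All
planted truth is returned alongside the cells, so every stage is validated by
parameter recovery. See `docs/methods.md` for the model and its defaults.

## Worked example

```python
import dataclasses
from tmacyto import preset, simulate_cohort
from tmacyto.pipeline import stage_gate, stage_quantify

spec = dataclasses.replace(preset("pdac-like"), n_patients=12)
cohort = simulate_cohort(spec, seed=3)
table = cohort.as_cell_table()
thresholds, calls = stage_gate(table)          # negative-control gating
summaries, comparisons = stage_quantify(calls, table.meta)
```

Running `python examples/03_quantify.py` (the script around the code above)
prints:

```
mean CD8+|CD3+ proportion: tumor 38.5% vs normal 53.7%
density_cd3: tumor 107 vs normal 140 (t = -10.15, p = 2.5e-09)
ratio_cd68_cd3: tumor 0.834 vs normal 0.541 (t = 10.05, p = 2.9e-09)
ratio_foxp3_cd8: tumor 0.44 vs normal 0.141 (t = 8.93, p = 2e-08)
```

Tumor cores show the planted immunosuppressive shift: a lower CD8 share of
the T-cell compartment and lower T-cell density, with elevated
macrophage-to-T-cell and Treg-to-cytotoxic ratios. The other scripts in
`examples/` walk through simulation, gating accuracy, proximity bands and
survival stratification the same way; `tmacyto run --preset pdac-like
--seed 1 --outdir out/` performs the whole analysis from the shell and writes
every intermediate plus a `report.md`.

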