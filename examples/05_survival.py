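"""Survival stratification: median splits, four-group cluster, Cox model.

Per-patient statistics come from the gated tumor cores; the hazard in the
generator depends on the true PD-1+|CD8+ and PD-L1+|CD68+ fractions, so the
proportion-based splits should separate survival while raw densities do not.
"""

import dataclasses

from tmacyto import preset, simulate_cohort
from tmacyto.pipeline import patient_statistics, stage_gate, stage_quantify
from tmacyto.survival import cox_fit, four_group_split, logrank_test, median_split

spec = dataclasses.replace(preset("pdac-like"), n_patients=84, normal_comp=None)
cohort = simulate_cohort(spec, seed=21)
table = cohort.as_cell_table()
_, calls = stage_gate(table)
summaries, _ = stage_quantify(calls, table.meta)
pts = patient_statistics(summaries, table.meta)

for stat in ("p_pd1_of_cd8", "density_cd3_cd8"):
    split = median_split(pts[stat])
    sub = pts.loc[split.labels.index]
    lr = logrank_test(sub["survival_months"], sub["event"], split.labels)
    print(f"median split on {stat}: log-rank p = {lr.p:.3g}")

labels, _ = four_group_split(pts["p_pd1_of_cd8"], pts["p_pdl1_of_cd68"])
sub = pts.loc[labels.index].copy()
sub["cluster"] = (labels == "high/high").astype(int)
fit = cox_fit(sub, ["cluster", "age", "sex_male", "stage"])
row = fit.summary.loc["cluster"]
print(f"\nCox (cluster = high/high on both proportions, vs rest):")
print(f"  HR = {row['hr']:.2f} [{row['hr_lo']:.2f}-{row['hr_hi']:.2f}], p = {row['p']:.3g}")
print("\nThe proportion split separates survival while the density split does")
print("not — the planted contrast. The cluster HR estimates the planted ~2x")
print("hazard of the double-high phenotype; a single 84-patient cohort is")
print("noisy, so individual runs scatter around it (see the replicate-level")
print("checks in the test suite).")
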