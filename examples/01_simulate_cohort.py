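"""Simulate a small synthetic TMA cohort and look at what it contains.

Each patient contributes a 1.5 mm tumor core (most also a paired
adjacent-normal core); one negative-control slide provides the gating
reference. Ground truth (planted phenotypes and per-patient subset
proportions) rides along for validation.
"""

import dataclasses

from tmacyto import preset, simulate_cohort

spec = dataclasses.replace(preset("pdac-like"), n_patients=8)
cohort = simulate_cohort(spec, seed=42)

print(f"samples: {cohort.meta['sample_id'].nunique()} "
      f"({(cohort.meta.tissue_class == 'tumor').sum()} tumor, "
      f"{(cohort.meta.tissue_class == 'adjacent_normal').sum()} normal, "
      f"{(cohort.meta.tissue_class == 'negative_control').sum()} control)")
print(f"total cells: {len(cohort.cells)}")
print("\nplanted per-patient fractions (first 4 patients):")
cols = ["patient_id", "prop_pd1_cd8", "prop_pdl1_cd68", "survival_months", "event"]
print(cohort.patient_truth[cols].head(4).round(3).to_string(index=False))
print("\nEach row is one patient's true PD-1+|CD8+ and PD-L1+|CD68+ fractions —")
print("the quantities the gating pipeline must later recover from intensities —")
print("plus the exponential-hazard survival time generated from them.")
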