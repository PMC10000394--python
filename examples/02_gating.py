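"""Negative-control thresholding and hierarchical phenotype assignment.

Thresholds sit at the 99th percentile of the unstained control intensities;
a cell is positive for a marker when its intensity strictly exceeds the
threshold, and the ordered gating rules turn positivity vectors into one
phenotype label per DAPI+ cell.
"""

from tmacyto import (
    CompositionParams,
    assign_phenotypes,
    call_positivity,
    estimate_thresholds,
    simulate_core,
    simulate_negative_control,
)

comp = CompositionParams(
    {"tumor": 400, "helper_t": 45, "cytotoxic_t": 40, "treg": 18,
     "macrophage": 80, "other": 150}
)
cells, truth = simulate_core(comp, seed=7)
control = simulate_negative_control(n_cells=2000, seed=8)

thresholds = estimate_thresholds(control, quantile=0.99)
print("thresholds (a.u.):",
      {m: round(t, 1) for m, t in thresholds.thresholds.items()})

calls = assign_phenotypes(call_positivity(cells, thresholds))
print("\nphenotype counts:", calls["phenotype"].value_counts().to_dict())

merged = calls.merge(truth, on=["sample_id", "cell_id"])
acc = (merged["phenotype"] == merged["true_phenotype"]).mean()
print(f"\nagreement with planted truth: {100 * acc:.1f}% of {len(merged)} cells")
print("Miscalls come almost entirely from the ~1% of negative cells whose")
print("intensity exceeds the control's 99th percentile by chance.")
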