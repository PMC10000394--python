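"""Distance-band proximity of PD-1+ vs PD-1− CD8 T cells around PD-L1+CD68+
macrophages.

Each CD8 T cell is assigned to a 10 µm band by the distance to its nearest
PD-L1+CD68+ macrophage. With attraction planted (kappa = 10) the PD-1+ subset
piles into the near bands while the PD-1− subset stays uniform.
"""

import dataclasses

from tmacyto import AttractionParams, preset, simulate_cohort
from tmacyto.pipeline import stage_gate, stage_proximity

spec = dataclasses.replace(
    preset("pdac-like"), n_patients=12, normal_comp=None,
    attraction=AttractionParams(kappa=10.0, sigma_um=15.0),
)
cohort = simulate_cohort(spec, seed=11)
table = cohort.as_cell_table()
_, calls = stage_gate(table)
_, tests = stage_proximity(calls, table.meta)

print("band        PD-1+ mean%   PD-1- mean%   p        ")
for _, row in tests["pdl1_pos_cd68"].iterrows():
    print(f"{row['band']:<10}  {row['mean_a']:>10.2f}  {row['mean_b']:>11.2f}  "
          f"{row['p']:.2g} {row['stars']}")
print("\nmean_a/mean_b are cross-sample means of per-sample band percentages;")
print("stars mark bands where the PD-1+ and PD-1- distributions differ (t-test).")
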