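import dataclasses

import numpy as np
import pandas as pd
import pytest

import tmacyto as tc
from tmacyto import pipeline, simulate


def bruteforce_band_profile(query_xy, ref_xy, max_radius=100.0, n_bands=10):
    """Independent O(n^2) oracle: nearest-reference distances by exhaustive
    scan, binned with explicit half-open interval tests."""
    q = np.asarray(query_xy, float)
    r = np.asarray(ref_xy, float)
    counts = np.zeros(n_bands, dtype=int)
    width = max_radius / n_bands
    dists = []
    for i in range(len(q)):
        best = np.inf
        for j in range(len(r)):
            d = np.hypot(q[i, 0] - r[j, 0], q[i, 1] - r[j, 1])
            if d < best:
                best = d
        dists.append(best)
        for b in range(n_bands):
            if b * width <= best < (b + 1) * width:
                counts[b] += 1
                break
    return counts, np.array(dists)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient pdac-like cohort shared by read-only tests."""
    spec = dataclasses.replace(simulate.preset("pdac-like"), n_patients=12)
    return simulate.simulate_cohort(spec, seed=1234)


@pytest.fixture(scope="session")
def gated_small_cohort(small_cohort):
    table = small_cohort.as_cell_table()
    thresholds, calls = pipeline.stage_gate(table)
    return small_cohort, table, thresholds, calls
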