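import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

import tmacyto as tc
from tmacyto.simulate import (
    NORMAL_DENSITIES,
    TUMOR_DENSITIES,
    ParameterError,
    preset,
    simulate_cohort,
    simulate_core,
    simulate_negative_control,
)

RADIUS_UM = 750.0


def _in_disc(cells, diameter_mm=1.5):
    r = diameter_mm * 1000 / 2
    dx = cells["x_um"].to_numpy() - r
    dy = cells["y_um"].to_numpy() - r
    return dx**2 + dy**2 <= r**2 + 1e-9


def test_zero_densities_give_empty_core():
    cells, truth = simulate_core(tc.CompositionParams({ph: 0.0 for ph in TUMOR_DENSITIES}), seed=0)
    assert len(cells) == 0 and len(truth) == 0


def test_invalid_diameter_raises():
    with pytest.raises(ParameterError):
        simulate_core(tc.CompositionParams({"other": 10.0}), diameter_mm=0.0)


def test_attraction_without_references_raises():
    comp = tc.CompositionParams(
        {"cytotoxic_t": 50.0, "macrophage": 0.0}, p_pd1_given_cd8=0.5
    )
    with pytest.raises(ParameterError):
        simulate_core(comp, attraction=tc.AttractionParams(kappa=5.0), seed=0)


def test_poisson_mean_cell_count():
    """Total density 500/mm^2 on a 1.5 mm disc: mean count over 100 seeds
    within 3 standard errors of the analytic 500 * pi * 0.75^2 = 883.6."""
    comp = tc.CompositionParams({"other": 500.0})
    counts = [len(simulate_core(comp, seed=s)[0]) for s in range(100)]
    expected = 500.0 * math.pi * 0.75**2
    se = math.sqrt(expected / 100)
    assert abs(np.mean(counts) - expected) < 3 * se


def test_all_coordinates_inside_disc():
    comp = tc.CompositionParams(dict(TUMOR_DENSITIES))
    for kappa in (0.0, 10.0):
        cells, _ = simulate_core(
            comp, attraction=tc.AttractionParams(kappa=kappa, sigma_um=15.0), seed=5
        )
        assert _in_disc(cells).all()


def _nn_dist_pd1_to_ref(cells, truth):
    q = truth["true_cd3"] & truth["true_cd8"] & truth["true_pd1"]
    r = truth["true_cd68"] & truth["true_pdl1"]
    if q.sum() == 0 or r.sum() == 0:
        return np.nan
    qxy = cells.loc[q.to_numpy(), ["x_um", "y_um"]].to_numpy()
    rxy = cells.loc[r.to_numpy(), ["x_um", "y_um"]].to_numpy()
    return cdist(qxy, rxy).min(axis=1).mean()  # brute-force oracle


def test_attraction_shrinks_nearest_reference_distance():
    """kappa=10 pulls PD-1+CD8+ cells toward PD-L1+CD68+ cells in >= 95/100 seeds."""
    comp = tc.CompositionParams(dict(TUMOR_DENSITIES))
    wins = 0
    n_valid = 0
    for s in range(100):
        c0, t0 = simulate_core(comp, attraction=tc.AttractionParams(kappa=0.0), seed=s)
        c10, t10 = simulate_core(
            comp, attraction=tc.AttractionParams(kappa=10.0, sigma_um=15.0), seed=s
        )
        d0, d10 = _nn_dist_pd1_to_ref(c0, t0), _nn_dist_pd1_to_ref(c10, t10)
        if np.isnan(d0) or np.isnan(d10):
            continue
        n_valid += 1
        wins += d10 < d0
    assert n_valid >= 95
    assert wins / n_valid >= 0.95


def test_negative_control_shape_and_class():
    ctrl = simulate_negative_control(n_cells=100, seed=1)
    assert len(ctrl) == 100
    assert _in_disc(ctrl).all()
    with pytest.raises(ParameterError):
        simulate_negative_control(n_cells=0)


def test_negative_control_tail_quantile_matches_lognormal():
    """Empirical 99th percentile of control CD8 ~ exp(mu + 2.326 sigma)."""
    ctrl = simulate_negative_control(n_cells=50_000, seed=2)
    q_emp = np.quantile(ctrl["cd8"], 0.99)
    q_true = math.exp(2.0 + 2.3263478740 * 0.5)
    assert q_emp == pytest.approx(q_true, rel=0.03)


def test_seed_determinism():
    a = simulate_negative_control(n_cells=500, seed=7)
    b = simulate_negative_control(n_cells=500, seed=7)
    pd.testing.assert_frame_equal(a, b)
    ca = simulate_cohort(dataclasses.replace(preset("pdac-like"), n_patients=3), seed=9)
    cb = simulate_cohort(dataclasses.replace(preset("pdac-like"), n_patients=3), seed=9)
    pd.testing.assert_frame_equal(ca.cells, cb.cells)
    pd.testing.assert_frame_equal(ca.patient_truth, cb.patient_truth)


def _clark_evans(xy, area_um2):
    d = cdist(xy, xy)
    np.fill_diagonal(d, np.inf)
    observed = d.min(axis=1).mean()
    expected = 0.5 / math.sqrt(len(xy) / area_um2)
    return observed / expected


def test_csr_when_no_attraction():
    """kappa=0: the PD-1+CD8+ pattern's Clark–Evans index matches that of
    freshly drawn uniform points (same n), averaged over seeds."""
    comp = tc.CompositionParams(dict(TUMOR_DENSITIES))
    area = math.pi * RADIUS_UM**2
    rng = np.random.default_rng(123)
    ce_pattern, ce_uniform = [], []
    for s in range(40):
        cells, truth = simulate_core(comp, attraction=tc.AttractionParams(kappa=0.0), seed=s)
        q = (truth["true_cd3"] & truth["true_cd8"] & truth["true_pd1"]).to_numpy()
        if q.sum() < 5:
            continue
        xy = cells.loc[q, ["x_um", "y_um"]].to_numpy()
        ce_pattern.append(_clark_evans(xy, area))
        # matched uniform reference on the same disc
        rr = RADIUS_UM * np.sqrt(rng.uniform(size=q.sum()))
        th = rng.uniform(0, 2 * math.pi, q.sum())
        uxy = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        ce_uniform.append(_clark_evans(uxy, area))
    diff = np.mean(ce_pattern) - np.mean(ce_uniform)
    se = math.sqrt(np.var(ce_pattern) / len(ce_pattern) + np.var(ce_uniform) / len(ce_uniform))
    assert abs(diff) < 4 * se


def test_cohort_shape_and_validation():
    spec = dataclasses.replace(preset("pdac-like"), n_patients=2)
    cohort = simulate_cohort(spec, seed=0)
    pts = cohort.meta.loc[cohort.meta["tissue_class"] != "negative_control", "patient_id"]
    assert pts.nunique() == 2
    with pytest.raises(ParameterError):
        dataclasses.replace(preset("pdac-like"), rho=1.5)
    with pytest.raises(ParameterError):
        dataclasses.replace(preset("pdac-like"), n_patients=1)


def test_pdac_preset_cohort_counts():
    """Default preset mirrors the cohort shape: 84 tumor + 73 paired normals."""
    spec = preset("pdac-like")
    assert spec.n_patients == 84
    assert int(round(spec.normal_fraction * spec.n_patients)) == 73


def test_estimated_proportions_track_truth(gated_small_cohort):
    """Gated per-sample PD-1+|CD8+ proportions agree with the planted
    per-patient fractions within binomial sampling error on average."""
    cohort, table, _, calls = gated_small_cohort
    from tmacyto import pipeline, quantify

    summaries, _ = pipeline.stage_quantify(calls, table.meta)
    tum = summaries[summaries["tissue_class"] == "tumor"].set_index("patient_id")
    truth = cohort.patient_truth.set_index("patient_id")
    est = tum["p_pd1_of_cd8"]
    true = truth.loc[est.index, "prop_pd1_cd8"]
    n_cd8 = tum["count_cd3_cd8"]
    z = (est - true) / np.sqrt(true * (1 - true) / n_cd8)
    # mean standardised error near 0, spread near 1 (loose MC bounds)
    assert abs(z.mean()) < 1.5
    assert z.abs().max() < 5
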