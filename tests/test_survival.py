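import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import tmacyto as tc
from tmacyto.survival import (
    SurvivalError,
    cox_fit,
    four_group_split,
    km_estimate,
    logrank_test,
    median_split,
    roc_1yr,
)


# ---------------------------------------------------------------------------
# median split


def test_median_split_even():
    s = median_split(pd.Series(range(1, 11), dtype=float))
    assert s.cutoff == 5.5
    assert (s.labels == "high").sum() == 5 and (s.labels == "low").sum() == 5


def test_median_split_ties_go_low():
    s = median_split(pd.Series([1.0, 2.0, 2.0, 3.0]))
    assert s.cutoff == 2.0
    assert list(s.labels) == ["low", "low", "low", "high"]


def test_median_split_odd_unique():
    s = median_split(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]))
    assert (s.labels == "high").sum() == 3  # (n-1)/2 strictly above the median


def test_median_split_degenerate_and_nan():
    with pytest.raises(SurvivalError):
        median_split(pd.Series([2.0, 2.0, 2.0, 2.0]))
    s = median_split(pd.Series([1.0, 2.0, 3.0, 4.0, np.nan]))
    assert s.n_excluded == 1


def test_four_group_partition():
    v1 = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    v2 = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
    labels, cutoffs = four_group_split(v1, v2)
    assert set(labels) <= {"high/high", "high/low", "low/high", "low/low"}
    assert len(labels) == 4


# ---------------------------------------------------------------------------
# Kaplan–Meier


def test_km_no_censoring_by_hand():
    km = km_estimate([1.0, 2.0, 3.0, 4.0], [True, True, True, True])
    assert np.allclose(km.survival_at([1.0, 2.0, 3.0, 4.0]), [0.75, 0.5, 0.25, 0.0])


def test_km_all_censored_flat_one():
    km = km_estimate([5.0, 8.0, 12.0], [False, False, False])
    assert np.allclose(km.survival_at([0.0, 6.0, 20.0]), 1.0)


def test_km_mixed_fixture_hand_computed():
    """Six records with interleaved censoring: product-limit by hand gives
    5/6, 5/8, 5/16, 0 after the four event times."""
    time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    event = [True, False, True, False, True, True]
    km = km_estimate(time, event)
    assert np.allclose(km.survival_at([1.0, 3.0, 5.0, 6.0]), [5 / 6, 5 / 8, 5 / 16, 0.0])


def test_km_curve_monotone_non_increasing():
    rng = np.random.default_rng(0)
    km = km_estimate(rng.exponential(20, 200), rng.uniform(size=200) < 0.6)
    assert (np.diff(km.survival) <= 1e-12).all()
    assert km.survival[0] <= 1.0 and km.survival_at(0.0) == 1.0


# ---------------------------------------------------------------------------
# log-rank


def _manual_logrank(t, e, g):
    """Independent O-E chi-square computation over pooled event times."""
    t, e, g = np.asarray(t, float), np.asarray(e, bool), np.asarray(g, bool)
    num = 0.0
    var = 0.0
    for tt in np.unique(t[e]):
        at1 = ((t >= tt) & g).sum()
        nj = (t >= tt).sum()
        dj = (e & (t == tt)).sum()
        d1 = (e & (t == tt) & g).sum()
        num += d1 - dj * at1 / nj
        if nj > 1:
            var += dj * (at1 / nj) * (1 - at1 / nj) * (nj - dj) / (nj - 1)
    return num**2 / var


def test_logrank_identical_groups_null():
    t = [2.0, 4.0, 6.0, 8.0]
    e = [True, True, False, True]
    res = logrank_test(t + t, e + e, ["A"] * 4 + ["B"] * 4)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_small_fixture_matches_manual_oe():
    t = [1.0, 3.0, 5.0, 7.0, 2.0, 4.0, 6.0, 8.0]
    e = [True, True, False, True, True, False, True, True]
    g = ["A"] * 4 + ["B"] * 4
    res = logrank_test(t, e, g)
    manual = _manual_logrank(t, e, np.array(g) == "A")
    assert res.statistic == pytest.approx(manual, rel=1e-9)
    assert res.p == pytest.approx(chi2.sf(manual, 1), rel=1e-9)


def test_logrank_relabel_invariance():
    rng = np.random.default_rng(1)
    t = rng.exponential(20, 60)
    e = rng.uniform(size=60) < 0.7
    g = np.where(rng.uniform(size=60) < 0.5, "x", "y")
    a = logrank_test(t, e, g)
    b = logrank_test(t, e, np.where(g == "x", "y", "x"))
    assert a.statistic == pytest.approx(b.statistic)


def test_logrank_errors():
    with pytest.raises(SurvivalError):
        logrank_test([1.0, 2.0], [True, True], ["A", "A"])


def test_logrank_k_group_form():
    rng = np.random.default_rng(2)
    t = rng.exponential(20, 80)
    e = rng.uniform(size=80) < 0.7
    g = rng.choice(list("abcd"), 80)
    res = logrank_test(t, e, g)
    assert res.df == 3 and res.statistic >= 0


# ---------------------------------------------------------------------------
# Cox


def test_cox_null_coverage_permuted_covariate():
    """A covariate permuted against outcomes: the 95% CI contains HR=1 in
    roughly 95% of replicates."""
    rng = np.random.default_rng(3)
    model = tc.SurvivalModel(coefficients={}, reference={})
    cover = 0
    N = 100
    for _ in range(N):
        covs = pd.DataFrame({"x": rng.normal(size=120)})
        d = tc.simulate_survival_data(covs, model, rng)
        d["x"] = rng.permutation(d["x"].to_numpy())
        fit = cox_fit(d, ["x"])
        row = fit.summary.loc["x"]
        cover += row["hr_lo"] <= 1.0 <= row["hr_hi"]
    assert 0.88 <= cover / N <= 1.0


def test_cox_binary_covariate_matches_rate_ratio():
    """Two-group exponential data: the Cox HR agrees with the event-rate
    ratio estimator (d1/T1)/(d0/T0)."""
    rng = np.random.default_rng(4)
    n = 2000
    g = (rng.uniform(size=n) < 0.5).astype(int)
    rate = 0.03 * np.exp(math.log(2) * g)
    d = pd.DataFrame(
        {"survival_months": rng.exponential(1 / rate), "event": True, "g": g}
    )
    fit = cox_fit(d, ["g"])
    rr = (
        d.loc[d.g == 1, "event"].sum() / d.loc[d.g == 1, "survival_months"].sum()
    ) / (d.loc[d.g == 0, "event"].sum() / d.loc[d.g == 0, "survival_months"].sum())
    assert math.log(fit.summary.loc["g", "hr"]) == pytest.approx(math.log(rr), abs=0.05)


def test_cox_constant_covariate_rejected():
    d = pd.DataFrame(
        {"survival_months": [1.0, 2.0, 3.0, 4.0], "event": [True] * 4, "x": 1.0}
    )
    with pytest.raises(SurvivalError):
        cox_fit(d, ["x"])


def test_cox_ci_brackets_hr():
    rng = np.random.default_rng(5)
    covs = pd.DataFrame({"x": rng.normal(size=200)})
    model = tc.SurvivalModel(coefficients={"x": 0.5}, reference={"x": 0.0})
    d = tc.simulate_survival_data(covs, model, rng)
    fit = cox_fit(d, ["x"])
    row = fit.summary.loc["x"]
    assert row["hr_lo"] < row["hr"] < row["hr_hi"]
    assert row["hr"] == pytest.approx(math.exp(row["coef"]))


# ---------------------------------------------------------------------------
# 1-year ROC


def _records(times, events, **preds):
    return pd.DataFrame({"survival_months": times, "event": events, **preds})


def test_roc_perfect_separation():
    r = _records([2.0] * 5 + [30.0] * 5, [True] * 5 + [False] * 5,
                 score=[9, 8, 7, 6, 5, 4, 3, 2, 1, 0])
    res = roc_1yr(r, ["score"])["score"]
    assert res.auc == pytest.approx(1.0)


def test_roc_constant_score_half():
    r = _records([2.0] * 5 + [30.0] * 5, [True] * 5 + [False] * 5, score=[1.0] * 10)
    assert roc_1yr(r, ["score"])["score"].auc == pytest.approx(0.5)


def test_roc_matches_mann_whitney_rank_oracle():
    rng = np.random.default_rng(6)
    times = np.concatenate([rng.uniform(1, 11, 4), rng.uniform(13, 60, 6)])
    events = np.concatenate([np.ones(4, bool), np.zeros(6, bool)])
    score = rng.normal(size=10)
    res = roc_1yr(_records(times, events, score=score), ["score"])["score"]
    pos = score[times < 12]
    neg = score[times >= 12]
    u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert res.auc == pytest.approx(u / (len(pos) * len(neg)))


def test_roc_excludes_early_censored():
    r = _records([2.0, 5.0, 3.0, 30.0, 40.0, 50.0],
                 [True, False, True, False, False, False],
                 score=[5, 4, 3, 2, 1, 0])
    res = roc_1yr(r, ["score"])["score"]
    assert res.n_excluded == 1   # censored at 5 months: outcome unknown
    assert res.n == 5


def test_roc_single_class_undefined():
    r = _records([30.0] * 6, [False] * 6, score=range(6))
    assert not roc_1yr(r, ["score"])["score"].defined
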