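"""Prognostic layer: median-cutoff stratification, Kaplan–Meier, log-rank,
Cox proportional hazards, and 1-year ROC.

The estimation itself is delegated to lifelines (product-limit KM, log-rank
chi-square, Cox partial likelihood with Efron tie handling) and scikit-learn
(empirical ROC / trapezoidal AUC); this module supplies the stratification
conventions used throughout:

* high/low groups split at the cohort median, with ties at the median going
  to "low" (strictly-greater-than rule) and undefined statistics excluded;
* four-group clusters from the cross of two median splits;
* the 1-year ROC dichotomises outcome at 12 months, excluding patients
  censored before 12 months (logged) — a deliberate, documented convention,
  not a time-dependent ROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test as _ll_mv_logrank
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

logger = logging.getLogger(__name__)


class SurvivalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# stratification


@dataclass
class MedianSplit:
    """High/low labels at the cohort median (ties at the median -> low)."""

    labels: pd.Series          # "high" / "low", indexed like the input
    cutoff: float
    n_excluded: int = 0


def median_split(values: pd.Series | np.ndarray) -> MedianSplit:
    v = pd.Series(values).astype(float)
    defined = v[np.isfinite(v)]
    n_excluded = len(v) - len(defined)
    if n_excluded:
        logger.info("median_split: excluding %d patients with undefined statistic", n_excluded)
    if len(defined) < 4:
        raise SurvivalError("median split needs at least 4 defined values")
    cutoff = float(defined.median())
    if defined.nunique() == 1:
        raise SurvivalError("degenerate split: all values identical")
    labels = pd.Series(
        np.where(defined > cutoff, "high", "low"), index=defined.index, name="group"
    )
    return MedianSplit(labels=labels, cutoff=cutoff, n_excluded=n_excluded)


def four_group_split(values_1, values_2) -> tuple[pd.Series, dict[str, float]]:
    """Cross of two median splits -> labels in {high/high, high/low, low/high,
    low/low}; patients undefined in either statistic are excluded."""
    s1 = median_split(values_1)
    s2 = median_split(values_2)
    idx = s1.labels.index.intersection(s2.labels.index)
    labels = s1.labels.loc[idx] + "/" + s2.labels.loc[idx]
    labels.name = "group"
    return labels, {"cutoff_1": s1.cutoff, "cutoff_2": s2.cutoff}


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass
class KMCurve:
    """Product-limit survival estimate, evaluable at arbitrary times."""

    times: np.ndarray          # unique event/censor times (including 0)
    survival: np.ndarray       # S(t) just after each time
    n_at_risk: np.ndarray
    n_events: int
    n: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation of S(t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.survival) - 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "n_at_risk": self.n_at_risk}
        )


def km_estimate(time, event) -> KMCurve:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if len(t) == 0:
        raise SurvivalError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(timeline).ffill().to_numpy(dtype=float)
    )
    return KMCurve(times=timeline, survival=surv, n_at_risk=at_risk,
                   n_events=int(e.sum()), n=len(t))


# ---------------------------------------------------------------------------
# log-rank


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p: float
    df: int
    groups: tuple[str, ...]


def logrank_test(time, event, groups) -> LogrankResult:
    """Standard (unweighted) log-rank; k-group generalisation when more than
    two group labels are present."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    g = np.asarray(groups)
    levels = [lv for lv in pd.unique(g)]
    if len(levels) < 2:
        raise SurvivalError("log-rank needs at least 2 groups")
    for lv in levels:
        if (g == lv).sum() == 0:
            raise SurvivalError(f"group {lv!r} has zero subjects")
    if len(levels) == 2:
        m0, m1 = g == levels[0], g == levels[1]
        res = _ll_logrank(t[m0], t[m1], e[m0], e[m1])
        df = 1
    else:
        res = _ll_mv_logrank(t, g, e)
        df = len(levels) - 1
    return LogrankResult(
        statistic=float(res.test_statistic), p=float(res.p_value), df=df,
        groups=tuple(str(lv) for lv in levels),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """Multivariate Cox fit: per-covariate HRs with Wald 95% CIs and p-values,
    renderable as a forest-plot table."""

    summary: pd.DataFrame      # index: covariate; coef, hr, hr_lo, hr_hi, se, p
    log_likelihood: float
    n: int
    n_events: int

    def forest_table(self) -> pd.DataFrame:
        return self.summary[["hr", "hr_lo", "hr_hi", "p"]].copy()


def cox_fit(records: pd.DataFrame, covariates: list[str],
            duration_col: str = "survival_months", event_col: str = "event") -> CoxFit:
    """Proportional-hazards partial-likelihood fit (Efron tie handling).

    Warns below 10 events; constant covariates are rejected up front since the
    partial likelihood cannot identify them.
    """
    df = records[[duration_col, event_col] + covariates].dropna()
    n_events = int(df[event_col].sum())
    if n_events < 10:
        logger.warning("cox_fit: only %d events; estimates may be unstable", n_events)
    for c in covariates:
        if df[c].nunique() <= 1:
            raise SurvivalError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()  # lifelines default tie handling is Efron
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_lo": s["exp(coef) lower 95%"],
            "hr_hi": s["exp(coef) upper 95%"],
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
    return CoxFit(summary=summary, log_likelihood=float(cph.log_likelihood_),
                  n=len(df), n_events=n_events)


# ---------------------------------------------------------------------------
# 1-year ROC


@dataclass
class RocResult:
    predictor: str
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n: int
    n_excluded: int
    defined: bool = True


def roc_1yr(records: pd.DataFrame, predictors: list[str],
            duration_col: str = "survival_months", event_col: str = "event",
            horizon: float = 12.0) -> dict[str, RocResult]:
    """Empirical ROC and trapezoidal AUC for 1-year mortality per predictor.

    Outcome: death before ``horizon`` months (positive) versus survival past
    it (negative); patients censored before the horizon are excluded (logged).
    Binary/categorical predictors should be passed numerically encoded.
    """
    t = records[duration_col].to_numpy(dtype=float)
    e = records[event_col].to_numpy(dtype=bool)
    known = (t >= horizon) | e
    n_excluded = int((~known).sum())
    if n_excluded:
        logger.info("roc_1yr: excluding %d patients censored before %g months",
                    n_excluded, horizon)
    y = (t < horizon) & e
    out: dict[str, RocResult] = {}
    for pred in predictors:
        x = records[pred].to_numpy(dtype=float)
        ok = known & np.isfinite(x)
        yi, xi = y[ok], x[ok]
        if len(np.unique(yi)) < 2:
            logger.info("roc_1yr: predictor %r has a single outcome class; AUC undefined", pred)
            out[pred] = RocResult(pred, np.nan, np.empty(0), np.empty(0),
                                  int(ok.sum()), n_excluded, defined=False)
            continue
        fpr, tpr, _ = _roc_curve(yi, xi)
        out[pred] = RocResult(pred, float(_auc(fpr, tpr)), fpr, tpr,
                              int(ok.sum()), n_excluded)
    return out
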