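"""Per-sample densities, subset proportions, ratios, and group statistics.

Counts come in two flavours per sample: hierarchical phenotype-label counts
(a partition of the DAPI+ cells) and marker-combination counts (e.g. CD3+CD8+,
used for the subset proportions, where a cell may contribute to several
combinations).  Densities divide counts by the tissue area; when the metadata
does not supply an area it is computed from the convex hull of the sample's
cells (the nominal disc area is available as an alternative).

Zero-denominator proportions are left undefined (NaN) and flagged, never
zero-filled, and are excluded from downstream group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull

from .gating import PHENOTYPES


class QuantificationError(ValueError):
    pass


#: marker combinations used for subset counts; name -> required positive markers
MARKER_COMBOS: dict[str, tuple[str, ...]] = {
    "cd3": ("cd3",),
    "cd3_cd8": ("cd3", "cd8"),
    "cd3_foxp3": ("cd3", "foxp3"),
    "cd3_cd8_pd1": ("cd3", "cd8", "pd1"),
    "cd68": ("cd68",),
    "cd68_pdl1": ("cd68", "pdl1"),
    "tumor": ("tumor_marker",),
    "tumor_pdl1": ("tumor_marker", "pdl1"),
}


def tissue_area_mm2(
    cells: pd.DataFrame,
    meta_row: pd.Series | dict | None = None,
    method: str = "convex_hull",
) -> float:
    """Tissue area for the density denominator.

    Order of precedence: a finite ``tissue_area_mm2`` in the metadata; else
    ``method='convex_hull'`` (hull of the sample's cell coordinates) or
    ``method='disc'`` (nominal pi*(d/2)^2 from ``core_diameter_mm``).
    """
    if meta_row is not None:
        area = meta_row.get("tissue_area_mm2", np.nan)
        if area is not None and np.isfinite(area):
            if area <= 0:
                raise QuantificationError("tissue area must be positive")
            return float(area)
    if method == "disc":
        d = float(meta_row.get("core_diameter_mm", 1.5)) if meta_row is not None else 1.5
        return math.pi * (d / 2.0) ** 2
    if method == "convex_hull":
        pts = cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(pts) < 3:
            raise QuantificationError(
                "cannot compute convex-hull area from fewer than 3 cells"
            )
        return float(ConvexHull(pts).volume) / 1e6  # µm^2 -> mm^2
    raise QuantificationError(f"unknown area method {method!r}")


def summarize_sample(
    calls: pd.DataFrame,
    meta_row: pd.Series | dict | None = None,
    area_method: str = "convex_hull",
) -> pd.Series:
    """Summarise one sample's phenotype calls into counts, densities,
    proportions and ratios.

    ``calls`` is the output of :func:`tmacyto.gating.assign_phenotypes` for one
    sample, optionally joined with the cell coordinates (needed only when the
    area must be computed from the convex hull).
    """
    if "sample_id" in calls.columns and calls["sample_id"].nunique() > 1:
        raise QuantificationError("summarize_sample expects calls from a single sample")
    area = tissue_area_mm2(calls, meta_row, method=area_method)
    if area <= 0:
        raise QuantificationError("tissue area must be positive")

    n_cells = len(calls)
    out: dict[str, float | str] = {}
    if "sample_id" in calls.columns and n_cells:
        out["sample_id"] = calls["sample_id"].iloc[0]
    elif meta_row is not None:
        out["sample_id"] = meta_row.get("sample_id", "")
    out["n_cells"] = n_cells
    out["tissue_area_mm2"] = area

    counts = calls["phenotype"].value_counts()
    for ph in PHENOTYPES:
        c = int(counts.get(ph, 0))
        out[f"count_{ph}"] = c
        out[f"density_{ph}"] = c / area

    combo_counts = {}
    for name, req in MARKER_COMBOS.items():
        mask = np.ones(n_cells, dtype=bool)
        for m in req:
            mask &= calls[m].to_numpy(dtype=bool)
        combo_counts[name] = int(mask.sum())
        out[f"count_{name}"] = combo_counts[name]
        out[f"density_{name}"] = combo_counts[name] / area

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else np.nan  # undefined, not zero

    out["p_cd8_of_cd3"] = ratio(combo_counts["cd3_cd8"], combo_counts["cd3"])
    out["p_pd1_of_cd8"] = ratio(combo_counts["cd3_cd8_pd1"], combo_counts["cd3_cd8"])
    out["p_pdl1_of_cd68"] = ratio(combo_counts["cd68_pdl1"], combo_counts["cd68"])
    out["p_pdl1_of_tumor"] = ratio(combo_counts["tumor_pdl1"], combo_counts["tumor"])
    out["p_pd1_cd8_of_all"] = ratio(combo_counts["cd3_cd8_pd1"], n_cells)
    out["p_pdl1_cd68_of_all"] = ratio(combo_counts["cd68_pdl1"], n_cells)
    out["ratio_cd68_cd3"] = ratio(combo_counts["cd68"], combo_counts["cd3"])
    out["ratio_foxp3_cd8"] = ratio(combo_counts["cd3_foxp3"], combo_counts["cd3_cd8"])
    return pd.Series(out)


def summarize_cohort(
    calls: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    area_method: str = "convex_hull",
) -> pd.DataFrame:
    """Per-sample summaries for every sample present in ``calls``."""
    meta_by_sample = (
        meta.set_index("sample_id", drop=False) if meta is not None else None
    )
    rows = []
    for sid, sub in calls.groupby("sample_id", sort=False):
        mrow = meta_by_sample.loc[sid] if meta_by_sample is not None else None
        rows.append(summarize_sample(sub, mrow, area_method=area_method))
    return pd.DataFrame(rows).reset_index(drop=True)


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test result with group summaries (for bar-plot style panels)."""

    t: float
    p: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    paired: bool = False
    welch: bool = False


def compare_groups(
    values_a, values_b, paired: bool = False, welch: bool = False
) -> GroupComparison:
    """Two-tailed t-test between two groups of per-sample statistics.

    Classic equal-variance Student form by default (``welch=True`` switches to
    the unequal-variance form).  Undefined values (NaN) are dropped first.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise QuantificationError("each group needs at least 2 defined values")
    if paired:
        if len(a) != len(b):
            raise QuantificationError("paired comparison needs equal-length groups")
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        t=float(t), p=float(p),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=float(stats.sem(a)), sem_b=float(stats.sem(b)),
        n_a=len(a), n_b=len(b), paired=paired, welch=welch,
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with the least-squares line and slope CI."""

    r: float
    p: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    n: int
    defined: bool = True


def cross_method_correlation(densities_a, densities_b) -> CorrelationResult:
    """Pearson r and fitted line between paired per-sample densities.

    Used to compare densities from two computation paths (e.g. gating-based
    versus ground-truth labels).  Pairs with an undefined member are dropped;
    zero variance in either vector yields an undefined (flagged) result.
    """
    a = np.asarray(densities_a, dtype=float)
    b = np.asarray(densities_b, dtype=float)
    if len(a) != len(b):
        raise QuantificationError("paired vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise QuantificationError("need at least 3 defined pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan,
                                 (np.nan, np.nan), len(a), defined=False)
    fit = stats.linregress(a, b)
    tcrit = stats.t.ppf(0.975, len(a) - 2)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return CorrelationResult(
        r=float(fit.rvalue), p=float(fit.pvalue),
        slope=float(fit.slope), intercept=float(fit.intercept),
        slope_ci=(float(ci[0]), float(ci[1])), n=len(a),
    )
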