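"""End-to-end orchestration: simulate -> gate -> quantify -> proximity ->
survival -> report.

Each stage is an importable function consuming and producing the documented
data frames, so stages are independently runnable (and the CLI subcommands are
thin wrappers).  :func:`run_pipeline` chains them, persists every intermediate
as CSV/JSON under the output directory, serialises the config for provenance,
and is fully determined by (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gating, proximity, quantify, simulate, survival
from .io import CellTable, read_cell_table, write_cell_table

logger = logging.getLogger(__name__)

#: query/reference positivity definitions for the proximity stage
PROXIMITY_SETS = {
    "pd1_pos_cd8": ("cd3", "cd8", "pd1"),
    "pd1_neg_cd8": ("cd3", "cd8", "!pd1"),
    "pdl1_pos_cd68": ("cd68", "pdl1"),
    "pdl1_neg_cd68": ("cd68", "!pdl1"),
}


@dataclass
class RunConfig:
    """Fully serialisable run configuration; (config, seed) determine outputs."""

    preset: str = "pdac-like"
    cells_path: str | None = None        # read these instead of simulating
    meta_path: str | None = None
    n_patients: int | None = None        # override the preset's cohort size
    seed: int = 0
    gating_quantile: float = 0.99
    band_max_radius_um: float = 100.0
    n_bands: int = 10
    proximity_metric: str = "nearest"
    area_method: str = "convex_hull"
    cluster_encoding: str = "binary"     # "binary" (high/high vs rest) or "four_level"
    outdir: str = "tmacyto_run"

    def band_spec(self) -> proximity.BandSpec:
        return proximity.BandSpec(self.band_max_radius_um, self.n_bands)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class PipelineError(RuntimeError):
    pass


def _mask(calls: pd.DataFrame, markers: tuple[str, ...]) -> np.ndarray:
    m = np.ones(len(calls), dtype=bool)
    for name in markers:
        if name.startswith("!"):
            m &= ~calls[name[1:]].to_numpy(dtype=bool)
        else:
            m &= calls[name].to_numpy(dtype=bool)
    return m


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> simulate.CohortData:
    spec = simulate.preset(config.preset)
    if config.n_patients is not None:
        spec = dataclasses.replace(spec, n_patients=config.n_patients)
    return simulate.simulate_cohort(spec, seed=config.seed)


def stage_gate(table: CellTable, quantile: float = 0.99) -> tuple[gating.ThresholdSet, pd.DataFrame]:
    """Threshold on the cohort's negative-control sample and call phenotypes.

    Returns the threshold set and a calls frame (positivity + phenotype label,
    with coordinates carried along for the spatial and area computations).
    """
    if table.meta is None:
        raise PipelineError("gating stage needs sample metadata to find the negative control")
    ctrl_ids = table.meta.loc[table.meta["tissue_class"] == "negative_control", "sample_id"]
    if len(ctrl_ids) == 0:
        raise PipelineError("no negative_control sample in metadata")
    ctrl = table.cells[table.cells["sample_id"].isin(ctrl_ids)]
    thresholds = gating.estimate_thresholds(ctrl, quantile=quantile)
    tissue = table.cells[~table.cells["sample_id"].isin(ctrl_ids)]
    pos = gating.call_positivity(tissue, thresholds)
    calls = gating.assign_phenotypes(pos)
    calls = calls.join(tissue[["x_um", "y_um"]])
    return thresholds, calls


def stage_quantify(calls: pd.DataFrame, meta: pd.DataFrame,
                   area_method: str = "convex_hull") -> tuple[pd.DataFrame, dict]:
    """Per-sample summaries plus tumor versus adjacent-normal comparisons."""
    summaries = quantify.summarize_cohort(calls, meta, area_method=area_method)
    summaries = summaries.merge(
        meta[["sample_id", "patient_id", "tissue_class"]], on="sample_id", how="left"
    )
    tum = summaries[summaries["tissue_class"] == "tumor"]
    nor = summaries[summaries["tissue_class"] == "adjacent_normal"]
    comparisons = {}
    if len(tum) >= 2 and len(nor) >= 2:
        for stat in (
            "density_cd3", "density_cd3_cd8", "density_cd3_foxp3", "density_cd68",
            "ratio_cd68_cd3", "ratio_foxp3_cd8", "p_cd8_of_cd3", "p_pd1_of_cd8",
            "p_pdl1_of_cd68",
        ):
            res = quantify.compare_groups(tum[stat], nor[stat])
            comparisons[stat] = dataclasses.asdict(res)
    return summaries, comparisons


def stage_proximity(calls: pd.DataFrame, meta: pd.DataFrame,
                    spec: proximity.BandSpec | None = None,
                    metric: str = "nearest") -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-tumor-sample band profiles of PD-1+/PD-1− CD8 T cells around
    PD-L1+ and PD-L1− CD68 macrophages, with per-band cross-sample tests."""
    spec = spec or proximity.BandSpec()
    tumor_ids = meta.loc[meta["tissue_class"] == "tumor", "sample_id"]
    profiles: dict[tuple[str, str], list[proximity.ProximityProfile]] = {}
    frames = []
    for sid in tumor_ids:
        sub = calls[calls["sample_id"] == sid]
        for qname in ("pd1_pos_cd8", "pd1_neg_cd8"):
            for rname in ("pdl1_pos_cd68", "pdl1_neg_cd68"):
                prof = proximity.proximity_profile(
                    sub, _mask(sub, PROXIMITY_SETS[qname]),
                    _mask(sub, PROXIMITY_SETS[rname]),
                    spec, metric=metric, sample_id=sid, query=qname, reference=rname,
                )
                profiles.setdefault((qname, rname), []).append(prof)
                frames.append(prof.to_frame())
    tidy = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    tests = {}
    for rname in ("pdl1_pos_cd68", "pdl1_neg_cd68"):
        a = profiles.get(("pd1_pos_cd8", rname), [])
        b = profiles.get(("pd1_neg_cd8", rname), [])
        if a and b:
            tests[rname] = proximity.compare_profiles(a, b)
    return tidy, tests


def patient_statistics(summaries: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: tumor-core marker statistics joined with survival
    covariates (sex encoded as male indicator, stage ordinal)."""
    tum = summaries[summaries["tissue_class"] == "tumor"].copy()
    m = meta.set_index("sample_id")
    tum = tum.set_index("sample_id")
    for col in ("survival_months", "event", "age", "sex", "stage"):
        tum[col] = m[col]
    tum["sex_male"] = (tum["sex"] == "M").astype(int)
    out = tum.reset_index().set_index("patient_id")
    out["event"] = out["event"].astype(bool)
    return out


def stage_survival(summaries: pd.DataFrame, meta: pd.DataFrame,
                   cluster_encoding: str = "binary") -> dict:
    """Median-split stratifications, KM/log-rank, four-group cluster, 1-year
    ROC and the multivariate Cox model."""
    pts = patient_statistics(summaries, meta)
    results: dict = {"n_patients": int(len(pts)), "n_events": int(pts["event"].sum())}

    km_frames = {}
    strata = {}
    for stat in ("density_cd3", "density_cd3_cd8", "density_cd3_foxp3", "density_cd68",
                 "density_cd3_cd8_pd1", "density_cd68_pdl1",
                 "p_pd1_cd8_of_all", "p_pdl1_cd68_of_all",
                 "p_pd1_of_cd8", "p_pdl1_of_cd68"):
        try:
            split = survival.median_split(pts[stat])
        except survival.SurvivalError as err:
            results.setdefault("skipped_strata", {})[stat] = str(err)
            continue
        sub = pts.loc[split.labels.index]
        lr = survival.logrank_test(sub["survival_months"], sub["event"], split.labels)
        strata[stat] = {
            "cutoff": split.cutoff,
            "n_high": int((split.labels == "high").sum()),
            "n_low": int((split.labels == "low").sum()),
            "logrank_statistic": lr.statistic,
            "logrank_p": lr.p,
        }
        for lv in ("high", "low"):
            grp = sub[split.labels == lv]
            km = survival.km_estimate(grp["survival_months"], grp["event"])
            km_frames[f"{stat}_{lv}"] = km.to_frame()
    results["median_splits"] = strata

    # four-group cluster on the two functional proportions
    labels, cutoffs = survival.four_group_split(pts["p_pd1_of_cd8"], pts["p_pdl1_of_cd68"])
    sub = pts.loc[labels.index]
    lr4 = survival.logrank_test(sub["survival_months"], sub["event"], labels)
    results["four_group"] = {
        "cutoffs": cutoffs,
        "group_sizes": labels.value_counts().to_dict(),
        "logrank_statistic": lr4.statistic,
        "logrank_p": lr4.p,
    }

    # cluster covariate for Cox / ROC
    if cluster_encoding == "binary":
        sub = sub.copy()
        sub["cluster"] = (labels == "high/high").astype(int)
    elif cluster_encoding == "four_level":
        order = {"low/low": 0, "low/high": 1, "high/low": 2, "high/high": 3}
        sub = sub.copy()
        sub["cluster"] = labels.map(order)
    else:
        raise PipelineError(f"unknown cluster encoding {cluster_encoding!r}")

    cox = survival.cox_fit(sub, ["cluster", "age", "sex_male", "stage"])
    results["cox"] = {
        "n": cox.n, "n_events": cox.n_events,
        "summary": cox.summary.round(6).to_dict(orient="index"),
    }

    rocs = survival.roc_1yr(sub, ["cluster", "age", "sex_male", "stage"])
    results["roc_1yr"] = {
        k: {"auc": r.auc, "n": r.n, "n_excluded": r.n_excluded, "defined": r.defined}
        for k, r in rocs.items()
    }
    results["_km_frames"] = km_frames
    results["_cox_summary"] = cox.summary
    results["_patients"] = sub
    return results


def _write_report(path: Path, comparisons: dict, tests: dict, surv: dict) -> None:
    lines = ["# tmacyto run report", ""]
    lines.append(f"Patients: {surv['n_patients']}; events: {surv['n_events']}")
    lines.append("")
    lines.append("## Tumor vs adjacent-normal comparisons (Student t)")
    for stat, res in comparisons.items():
        lines.append(
            f"- {stat}: tumor {res['mean_a']:.4g} ± {res['sem_a']:.2g} vs "
            f"normal {res['mean_b']:.4g} ± {res['sem_b']:.2g}, p = {res['p']:.3g}"
        )
    lines.append("")
    lines.append("## Proximity band tests (PD-1+ vs PD-1− CD8 T cells)")
    for rname, df in tests.items():
        sig = df.loc[df["p"] < 0.05, "band"].tolist()
        lines.append(f"- reference {rname}: significant bands {sig or 'none'}")
    lines.append("")
    lines.append("## Survival")
    for stat, res in surv["median_splits"].items():
        lines.append(f"- median split on {stat}: log-rank p = {res['logrank_p']:.3g}")
    lines.append(f"- four-group cluster log-rank p = {surv['four_group']['logrank_p']:.3g}")
    cox = surv["cox"]["summary"].get("cluster", {})
    if cox:
        lines.append(
            f"- Cox cluster HR = {cox['hr']:.3g} "
            f"[{cox['hr_lo']:.3g}–{cox['hr_hi']:.3g}], p = {cox['p']:.3g}"
        )
    for pred, r in surv["roc_1yr"].items():
        lines.append(f"- 1-year AUC ({pred}): {r['auc']:.3g}" if r["defined"]
                     else f"- 1-year AUC ({pred}): undefined")
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, persist intermediates under ``config.outdir``, and
    return the in-memory results."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    if config.cells_path is not None:
        table = read_cell_table(config.cells_path, config.meta_path)
        cohort = None
    else:
        cohort = stage_simulate(config)
        table = cohort.as_cell_table()
        write_cell_table(table, out / "cells.csv", out / "meta.csv")
        cohort.cell_truth.to_csv(out / "cell_truth.csv", index=False)
        cohort.patient_truth.to_csv(out / "patient_truth.csv", index=False)

    thresholds, calls = stage_gate(table, quantile=config.gating_quantile)
    thresholds.to_csv(out / "thresholds.csv")
    calls.to_csv(out / "phenotype_calls.csv", index=False)

    summaries, comparisons = stage_quantify(calls, table.meta, config.area_method)
    summaries.to_csv(out / "sample_summaries.csv", index=False)
    (out / "group_comparisons.json").write_text(json.dumps(comparisons, indent=2))

    tidy, tests = stage_proximity(calls, table.meta, config.band_spec(),
                                  metric=config.proximity_metric)
    tidy.to_csv(out / "proximity_profiles.csv", index=False)
    for rname, df in tests.items():
        df.to_csv(out / f"proximity_tests_{rname}.csv", index=False)

    surv = stage_survival(summaries, table.meta, config.cluster_encoding)
    for name, km in surv.pop("_km_frames").items():
        km.to_csv(out / f"km_{name}.csv", index=False)
    surv.pop("_cox_summary").to_csv(out / "cox_forest.csv")
    surv.pop("_patients").to_csv(out / "patient_statistics.csv")
    (out / "survival.json").write_text(json.dumps(surv, indent=2, default=float))

    _write_report(out / "report.md", comparisons, tests, surv)
    return {
        "cohort": cohort, "thresholds": thresholds, "calls": calls,
        "summaries": summaries, "comparisons": comparisons,
        "proximity_profiles": tidy, "proximity_tests": tests, "survival": surv,
    }
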