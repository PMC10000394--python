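"""Flow-cytometry-like gating of per-cell intensities.

Two steps mirror the image-cytometry workflow: (1) per-marker positivity
thresholds set from a negative-control sample (an empirical quantile of the
control intensities, default 0.99), and (2) hierarchical phenotype assignment
from the resulting positivity vectors.

The hierarchy is expressed as an ordered rule list (first match wins), so the
precedence is explicit and alternative trees can be tested.  The default tree:

* tumor-marker+ cells are Tumor (PD-L1_Tumor if also PD-L1+), regardless of
  immune markers;
* else the CD3 branch: CD8+ -> Cytotoxic_T (Exhausted_cytotoxic_T if PD-1+),
  FOXP3+ (CD8−) -> Treg, otherwise T_cell.  CD8 outranks FOXP3 for rare
  CD8+FOXP3+ vectors;
* else CD68+ -> Macrophage (PD-L1_Macrophage if PD-L1+);
* else Other.

PD-1 on non-CD8 cells and PD-L1 on T cells are retained in the positivity
vectors but create no label, matching conventional sequential gating.
Positivity is strict (intensity > threshold): a cell exactly at the threshold
is negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellTable
from .markers import MARKER_NAMES

logger = logging.getLogger(__name__)

PHENOTYPES: tuple[str, ...] = (
    "Tumor",
    "PD-L1_Tumor",
    "T_cell",
    "Cytotoxic_T",
    "Exhausted_cytotoxic_T",
    "Treg",
    "Macrophage",
    "PD-L1_Macrophage",
    "Other",
)

#: Ordered gating rules: first rule whose ``all_of`` markers are all positive
#: and ``none_of`` all negative assigns its label.  Order encodes precedence.
DEFAULT_GATING_RULES: tuple[dict, ...] = (
    {"label": "PD-L1_Tumor", "all_of": ("tumor_marker", "pdl1"), "none_of": ()},
    {"label": "Tumor", "all_of": ("tumor_marker",), "none_of": ()},
    {"label": "Exhausted_cytotoxic_T", "all_of": ("cd3", "cd8", "pd1"), "none_of": ()},
    {"label": "Cytotoxic_T", "all_of": ("cd3", "cd8"), "none_of": ()},
    {"label": "Treg", "all_of": ("cd3", "foxp3"), "none_of": ()},
    {"label": "T_cell", "all_of": ("cd3",), "none_of": ()},
    {"label": "PD-L1_Macrophage", "all_of": ("cd68", "pdl1"), "none_of": ()},
    {"label": "Macrophage", "all_of": ("cd68",), "none_of": ()},
)


class GatingError(ValueError):
    pass


@dataclass
class ThresholdSet:
    """Per-marker positivity cutoffs (a.u.) with provenance."""

    thresholds: dict[str, float]
    source_sample: str | None = None
    quantile: float | None = None
    n_control_cells: int | None = None

    def __getitem__(self, marker: str) -> float:
        return self.thresholds[marker]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": list(self.thresholds),
                "threshold": list(self.thresholds.values()),
                "source_sample": self.source_sample,
                "quantile": self.quantile,
                "n_control_cells": self.n_control_cells,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ThresholdSet":
        df = pd.read_csv(path)
        src = df["source_sample"].iloc[0] if "source_sample" in df else None
        q = float(df["quantile"].iloc[0]) if "quantile" in df else None
        n = int(df["n_control_cells"].iloc[0]) if "n_control_cells" in df else None
        return cls(dict(zip(df["marker"], df["threshold"])), src, q, n)


def estimate_thresholds(
    neg_control: CellTable | pd.DataFrame,
    quantile: float = 0.99,
    markers: tuple[str, ...] = MARKER_NAMES,
) -> ThresholdSet:
    """Set per-marker thresholds at an empirical quantile of negative-control cells.

    Uses the linear-interpolation (type-7) empirical quantile.  Fewer than 20
    control cells triggers a warning (the tail quantile is then poorly
    determined) but is not an error.
    """
    df = neg_control.cells if isinstance(neg_control, CellTable) else neg_control
    if len(df) == 0:
        raise GatingError("negative-control table is empty")
    if not 0.0 < quantile <= 1.0:
        raise GatingError(f"quantile must be in (0, 1], got {quantile}")
    if len(df) < 20:
        logger.warning(
            "negative control has only %d cells; threshold quantile %.3g is poorly determined",
            len(df),
            quantile,
        )
    src = None
    if "sample_id" in df.columns and len(df):
        ids = df["sample_id"].unique()
        src = ",".join(map(str, ids))
    thr = {}
    for m in markers:
        # The control slide omits the antibody stains but keeps the nuclear
        # counterstain, so its DAPI signal is *positive*: the DAPI gate uses
        # the lower-tail quantile (real nuclei must exceed it) while every
        # antibody marker uses the upper-tail quantile of its unstained noise.
        q = 1.0 - quantile if m == "dapi" else quantile
        thr[m] = float(np.quantile(df[m].to_numpy(dtype=float), q, method="linear"))
    return ThresholdSet(thr, source_sample=src, quantile=quantile, n_control_cells=len(df))


def call_positivity(
    table: CellTable | pd.DataFrame, thresholds: ThresholdSet
) -> pd.DataFrame:
    """Boolean positivity per cell per marker: intensity strictly above threshold."""
    df = table.cells if isinstance(table, CellTable) else table
    missing = [m for m in MARKER_NAMES if m in df.columns and m not in thresholds.thresholds]
    if missing:
        raise GatingError(f"ThresholdSet lacks thresholds for marker(s): {missing}")
    out = {}
    for m in MARKER_NAMES:
        if m in df.columns:
            out[m] = df[m].to_numpy(dtype=float) > thresholds[m]
    pos = pd.DataFrame(out, index=df.index)
    for key in ("sample_id", "cell_id"):
        if key in df.columns:
            pos.insert(0, key, df[key])
    return pos


def assign_phenotypes(
    positivity: pd.DataFrame,
    rules: tuple[dict, ...] = DEFAULT_GATING_RULES,
    default_label: str = "Other",
) -> pd.DataFrame:
    """Assign one hierarchical phenotype label per DAPI+ cell.

    Rows that are DAPI− are dropped (count logged): without a nuclear signal
    the event is not treated as a cell.  Returns the positivity frame
    (DAPI+ rows only) with a ``phenotype`` column appended.
    """
    if "dapi" not in positivity.columns:
        raise GatingError("positivity frame lacks a 'dapi' column")
    keep = positivity["dapi"].to_numpy(dtype=bool)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d DAPI-negative events before phenotype assignment", n_dropped)
    pos = positivity.loc[keep].copy()
    conds = []
    labels = []
    for rule in rules:
        mask = np.ones(len(pos), dtype=bool)
        for m in rule["all_of"]:
            mask &= pos[m].to_numpy(dtype=bool)
        for m in rule.get("none_of", ()):
            mask &= ~pos[m].to_numpy(dtype=bool)
        conds.append(mask)
        labels.append(rule["label"])
    pos["phenotype"] = np.select(conds, labels, default=default_label)
    return pos
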