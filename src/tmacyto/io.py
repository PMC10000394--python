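"""Cell-table and sample-metadata I/O (schema v1).

The on-disk format emulates a per-cell segmentation export: one CSV row per
segmented cell with its coordinates (µm) and one intensity (a.u.) per marker,
plus a separate per-sample metadata CSV.

Cell-table columns (fixed order)::

    sample_id, cell_id, x_um, y_um,
    dapi, cd3, cd8, foxp3, cd68, pd1, pdl1, tumor_marker

Metadata columns::

    sample_id, patient_id, tissue_class, core_diameter_mm, tissue_area_mm2,
    survival_months, event, age, sex, stage

Coordinate convention: x/y in µm, origin at the core bounding-box lower-left,
y increasing upward.  Segmentation platforms commonly export pixel-based,
y-down coordinates; :func:`read_cell_table` exposes ``pixel_size_um`` and
``flip_y`` to convert such exports on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MARKER_NAMES

CELL_COLUMNS: tuple[str, ...] = ("sample_id", "cell_id", "x_um", "y_um") + MARKER_NAMES

META_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "patient_id",
    "tissue_class",
    "core_diameter_mm",
    "tissue_area_mm2",
    "survival_months",
    "event",
    "age",
    "sex",
    "stage",
)

TISSUE_CLASSES = ("tumor", "adjacent_normal", "negative_control")

NUMERIC_CELL_COLUMNS: tuple[str, ...] = ("x_um", "y_um") + MARKER_NAMES


class CellTableError(ValueError):
    """Base class for cell-table format problems."""


class SchemaError(CellTableError):
    """A required column is missing or has the wrong dtype family."""


class ParseError(CellTableError):
    """A cell value could not be parsed as the documented type."""


class IntegrityError(CellTableError):
    """Cross-row or cross-table consistency violation."""


@dataclass
class CellTable:
    """Validated container: per-cell measurements plus per-sample metadata.

    ``cells`` holds one row per segmented cell; ``meta`` (optional) one row per
    sample_id.  Construction does not validate — call :meth:`validate` or go
    through :func:`read_cell_table`, which validates on ingest.
    """

    cells: pd.DataFrame
    meta: pd.DataFrame | None = None

    def validate(self) -> "CellTable":
        validate_cells(self.cells)
        if self.meta is not None:
            validate_meta(self.meta)
            orphans = set(self.cells["sample_id"]) - set(self.meta["sample_id"])
            if orphans:
                raise IntegrityError(
                    f"cells reference sample_id(s) missing from metadata: {sorted(orphans)}"
                )
        return self

    def sample(self, sample_id: str) -> pd.DataFrame:
        return self.cells[self.cells["sample_id"] == sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.cells["sample_id"]))

    def __len__(self) -> int:
        return len(self.cells)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.cells.reset_index(drop=True), other.cells.reset_index(drop=True)
            )
        except AssertionError:
            return False
        return True


def validate_cells(df: pd.DataFrame) -> None:
    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cell table is missing required column {col!r}")
    for col in NUMERIC_CELL_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ParseError(f"column {col!r} is not numeric")
        vals = df[col].to_numpy(dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            raise ParseError(
                f"non-finite value in column {col!r} at row {int(np.flatnonzero(bad)[0])}"
            )
    for col in MARKER_NAMES:
        vals = df[col].to_numpy(dtype=float)
        if (vals < 0).any():
            raise ParseError(
                f"negative intensity in column {col!r} at row "
                f"{int(np.flatnonzero(vals < 0)[0])}"
            )
    dup = df.duplicated(subset=["sample_id", "cell_id"])
    if dup.any():
        first = df.loc[dup, ["sample_id", "cell_id"]].iloc[0]
        raise IntegrityError(
            f"duplicate (sample_id, cell_id) = ({first['sample_id']!r}, {first['cell_id']!r})"
        )


def validate_meta(df: pd.DataFrame) -> None:
    for col in ("sample_id", "patient_id", "tissue_class"):
        if col not in df.columns:
            raise SchemaError(f"metadata table is missing required column {col!r}")
    bad = ~df["tissue_class"].isin(TISSUE_CLASSES)
    if bad.any():
        raise ParseError(
            f"unknown tissue_class {df.loc[bad, 'tissue_class'].iloc[0]!r}"
        )
    if df["sample_id"].duplicated().any():
        raise IntegrityError("duplicate sample_id in metadata")
    # negative controls carry no survival information
    if "survival_months" in df.columns:
        ctrl = df["tissue_class"] == "negative_control"
        if ctrl.any() and df.loc[ctrl, "survival_months"].notna().any():
            raise IntegrityError("negative_control samples must not carry survival fields")


def _coerce_numeric(df: pd.DataFrame, columns: tuple[str, ...]) -> pd.DataFrame:
    for col in columns:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric value {raw.iloc[i]!r} in column {col!r} at row {i}")
        df[col] = coerced.astype(float)
    return df


def read_cell_table(
    path,
    meta_path=None,
    *,
    pixel_size_um: float | None = None,
    flip_y: bool = False,
) -> CellTable:
    """Read a per-cell CSV (and optional metadata CSV) into a validated CellTable.

    ``pixel_size_um`` multiplies raw coordinates (for pixel-based exports);
    ``flip_y`` converts y-down exports to the package's y-up convention by
    reflecting about each sample's own y extent.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "cell_id": str})
    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cell table {path} is missing required column {col!r}")
    df = _coerce_numeric(df[list(CELL_COLUMNS)].copy(), NUMERIC_CELL_COLUMNS)
    if pixel_size_um is not None:
        df["x_um"] = df["x_um"] * pixel_size_um
        df["y_um"] = df["y_um"] * pixel_size_um
    if flip_y:
        df["y_um"] = df.groupby("sample_id")["y_um"].transform(lambda y: y.max() - y)
    meta = read_sample_meta(meta_path) if meta_path is not None else None
    table = CellTable(cells=df, meta=meta)
    table.validate()
    return table


def write_cell_table(table: CellTable, path, meta_path=None) -> None:
    """Write a CellTable back to CSV, fixed column order, full float precision."""
    table.cells[list(CELL_COLUMNS)].to_csv(path, index=False)
    if meta_path is not None and table.meta is not None:
        write_sample_meta(table.meta, meta_path)


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str, "sex": str})
    validate_meta(meta)
    return meta


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    cols = [c for c in META_COLUMNS if c in meta.columns]
    cols += [c for c in meta.columns if c not in cols]
    meta[cols].to_csv(path, index=False)
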