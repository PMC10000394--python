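"""Marker panel shared by every stage.

The panel is the eight-plex used throughout: a nuclear counterstain (DAPI),
lymphoid lineage markers (CD3, CD8, FOXP3), a myeloid lineage marker (CD68),
two checkpoint/functional markers (PD-1, PD-L1) and a tumor-cell marker
(PanCK/SOX10, stored as ``tumor_marker``).  Per-cell intensities are the mean
fluorescence over the marker's compartment: nuclear for DAPI and FOXP3,
cytoplasmic for everything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Compartment(str, Enum):
    NUCLEAR = "nuclear"
    CYTOPLASMIC = "cytoplasmic"


@dataclass(frozen=True)
class Marker:
    """A panel marker: column name plus the compartment its intensity is read from."""

    name: str
    compartment: Compartment


MARKERS: tuple[Marker, ...] = (
    Marker("dapi", Compartment.NUCLEAR),
    Marker("cd3", Compartment.CYTOPLASMIC),
    Marker("cd8", Compartment.CYTOPLASMIC),
    Marker("foxp3", Compartment.NUCLEAR),
    Marker("cd68", Compartment.CYTOPLASMIC),
    Marker("pd1", Compartment.CYTOPLASMIC),
    Marker("pdl1", Compartment.CYTOPLASMIC),
    Marker("tumor_marker", Compartment.CYTOPLASMIC),
)

MARKER_NAMES: tuple[str, ...] = tuple(m.name for m in MARKERS)

COMPARTMENT: dict[str, Compartment] = {m.name: m.compartment for m in MARKERS}
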