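"""SAM morphometrics: height, width, area and the parabola representation.

Height and width are measured on each of the two orthogonal side views of
a meristem from manually placed landmarks, following three rules: the
height runs along the apical–basal axis, the width is perpendicular to the
height, and the width is taken at the most apically visible primordium.
The two views are technical replicates of one meristem and are averaged.
The meristem area is the sum of the areas of the cells inside the
externally derived meristem boundary (negative Gaussian curvature rim).

For display, a meristem's shape is drawn as the canonical downward parabola
``y = H (1 − (2x/W)²)`` passing through (0, H) and (±W/2, 0), coloured by
the identity of the primordia formed at the SAM periphery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OrthoViewMeasure",
    "MorphRecord",
    "ShapeParabola",
    "PRIMORDIUM_IDENTITIES",
    "IDENTITY_COLORS",
    "measure_view",
    "merge_views",
    "shape_parabola",
    "meristem_area",
    "max_height_timepoint",
]

PRIMORDIUM_IDENTITIES = ("vegetative", "cauline", "floral")

#: plotting key for the primordium-identity classes
IDENTITY_COLORS = {"vegetative": "tab:green", "cauline": "tab:olive",
                   "floral": "tab:purple"}


@dataclass
class OrthoViewMeasure:
    """Height/width of one orthogonal view, with the landmarks used."""

    view: str
    height_um: float
    width_um: float
    apex_um: tuple[float, float]
    width_end1_um: tuple[float, float]
    width_end2_um: tuple[float, float]

    def __post_init__(self) -> None:
        if self.height_um <= 0 or self.width_um <= 0:
            raise ValueError("height and width must be positive")


@dataclass
class MorphRecord:
    """One meristem's morphometric summary (view means)."""

    genotype: str
    timepoint_d: float
    height_um: float
    width_um: float
    area_um2: float | None = None
    primordium_identity: str = "vegetative"
    experiment_id: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.primordium_identity not in PRIMORDIUM_IDENTITIES:
            raise ValueError(
                f"identity must be one of {PRIMORDIUM_IDENTITIES}, "
                f"got {self.primordium_identity!r}"
            )


@dataclass
class ShapeParabola:
    """Canonical parabola ``y = H (1 − (2x/W)²)`` representing SAM shape."""

    height_um: float
    width_um: float
    identity: str = "vegetative"

    def __post_init__(self) -> None:
        if self.height_um <= 0 or self.width_um <= 0:
            raise ValueError("H and W must be positive")

    @property
    def color(self) -> str:
        return IDENTITY_COLORS.get(self.identity, "gray")

    def evaluate(self, x_um) -> np.ndarray:
        x = np.asarray(x_um, dtype=float)
        return self.height_um * (1 - (2 * x / self.width_um) ** 2)

    @property
    def area_um2(self) -> float:
        """Area under the parabola, 2HW/3 (closed form)."""
        return 2.0 * self.height_um * self.width_um / 3.0


def measure_view(view: str, apex_um, end1_um, end2_um) -> OrthoViewMeasure:
    """Measure one side view from its landmarks (all points in μm).

    The width is the distance between the endpoints placed at the most
    apical visible primordium; the height is the perpendicular distance
    from the apex to the width line (so the two stay orthogonal even when
    the drawn width segment is not horizontal).  The second coordinate is
    depth (grows downward): the apex must lie above the width line.
    """
    apex = np.asarray(apex_um, dtype=float)
    e1 = np.asarray(end1_um, dtype=float)
    e2 = np.asarray(end2_um, dtype=float)
    d = e2 - e1
    width = float(np.hypot(*d))
    if width == 0:
        raise ValueError("width endpoints coincide")
    # unit normal to the width segment pointing upward (toward smaller depth)
    n = np.array([-d[1], d[0]]) / width
    if n[1] > 0:
        n = -n
    height = float(np.dot(apex - e1, n))
    if height <= 0:
        raise ValueError("apex lies on or below the width line")
    return OrthoViewMeasure(view, height, width, tuple(apex), tuple(e1), tuple(e2))


def merge_views(v1: OrthoViewMeasure, v2: OrthoViewMeasure | None = None,
                **record_fields) -> MorphRecord:
    """Average the two orthogonal views (technical replicates) of a meristem.

    With a single available view its values pass through unchanged and the
    record carries a provenance note.
    """
    if v2 is None:
        return MorphRecord(height_um=v1.height_um, width_um=v1.width_um,
                           note=f"single view ({v1.view})", **record_fields)
    return MorphRecord(
        height_um=0.5 * (v1.height_um + v2.height_um),
        width_um=0.5 * (v1.width_um + v2.width_um),
        note="",
        **record_fields,
    )


def shape_parabola(record: MorphRecord) -> ShapeParabola:
    """Parabola representation of one meristem's morphology."""
    return ShapeParabola(record.height_um, record.width_um,
                         record.primordium_identity)


def meristem_area(cells: pd.DataFrame) -> tuple[float, int]:
    """Sum the per-cell areas over the meristem members of a cell table.

    Returns ``(area_um2, cell_count)``; the cell count is the L1
    cell-number readout.  Expects columns ``area_um2`` and
    ``meristem_member``.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    member = cells["meristem_member"].astype(bool)
    if not member.any():
        warnings.warn("no meristem member cells; area is 0", stacklevel=2)
        return 0.0, 0
    return float(cells.loc[member, "area_um2"].sum()), int(member.sum())


def max_height_timepoint(records: pd.DataFrame, genotype: str,
                         experiment_id: str | None = None) -> float:
    """Timepoint at which the per-timepoint median height peaks.

    Ties are broken in favour of the earlier timepoint.
    """
    df = records[records["genotype"] == genotype]
    if experiment_id is not None:
        df = df[df["experiment_id"] == experiment_id]
    if len(df) == 0:
        raise ValueError(f"no records for genotype {genotype!r}")
    med = df.groupby("timepoint_d")["height_um"].median().sort_index()
    return float(med.idxmax())  # idxmax returns the first (earliest) maximum
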