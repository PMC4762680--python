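"""Wisconsin-template subfield quantification.

The grading template is a set of concentric circles of diameters 1000, 3000
and 6000 µm centered on the fovea, defining inner, middle and outer
subfields. Each segmented druse is assigned to exactly one subfield by its
centroid, and per-subfield drusen number, total equivalent diameter and
total area are accumulated; the ``all`` field (< 6000 µm) is the sum of the
three subfields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import DrusenMap

__all__ = ["GradingTemplate", "SubfieldMetrics", "build_template", "quantify", "FIELDS"]

#: Subfield outer radii in µm (from template diameters 1000 / 3000 / 6000 µm).
SUBFIELD_RADII_UM = (500.0, 1500.0, 3000.0)

FIELDS = ("inner", "middle", "outer", "all")


@dataclass(frozen=True)
class GradingTemplate:
    """The concentric grading grid placed on the fovea."""

    fovea_px: tuple[float, float]
    scale_um_per_px: float
    shape: tuple[int, int]
    radii_um: tuple[float, float, float] = SUBFIELD_RADII_UM

    def subfield_of(self, row: float, col: float) -> str:
        """Subfield containing a point, by Euclidean distance from the fovea."""
        d = np.hypot(row - self.fovea_px[0], col - self.fovea_px[1]) * self.scale_um_per_px
        r1, r2, r3 = self.radii_um
        if d < r1:
            return "inner"
        if d < r2:
            return "middle"
        if d < r3:
            return "outer"
        return "outside"

    def membership(self) -> np.ndarray:
        """Per-pixel subfield codes: 0 inner, 1 middle, 2 outer, 3 outside."""
        rr, cc = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        d = np.hypot(rr - self.fovea_px[0], cc - self.fovea_px[1]) * self.scale_um_per_px
        out = np.full(self.shape, 3, dtype=np.int8)
        r1, r2, r3 = self.radii_um
        out[d < r3] = 2
        out[d < r2] = 1
        out[d < r1] = 0
        return out

    def field_mask(self) -> np.ndarray:
        """Boolean mask of the analyzed < 6000 µm circle."""
        return self.membership() < 3


@dataclass(frozen=True)
class SubfieldMetrics:
    """Drusen number / total diameter / total area per subfield.

    ``table`` is indexed by field (inner, middle, outer, all) with columns
    ``number``, ``diameter_um``, ``area_um2``. The ``all`` row equals the
    sum of the three subfield rows exactly.
    """

    table: pd.DataFrame
    scale_um_per_px: float

    def __post_init__(self) -> None:
        if list(self.table.index) != list(FIELDS):
            raise ValueError(f"metrics table must be indexed by {FIELDS}")

    def value(self, metric: str, subfield: str) -> float:
        col = {"number": "number", "diameter": "diameter_um", "area": "area_um2"}[metric]
        return float(self.table.loc[subfield, col])

    @classmethod
    def zeros(cls, scale_um_per_px: float) -> "SubfieldMetrics":
        table = pd.DataFrame(
            0.0, index=list(FIELDS), columns=["number", "diameter_um", "area_um2"]
        )
        return cls(table=table, scale_um_per_px=scale_um_per_px)


def build_template(
    fovea_px: tuple[float, float],
    scale_um_per_px: float,
    shape: tuple[int, int],
) -> GradingTemplate:
    """Place the grading template; the fovea must lie inside the raster."""
    r, c = fovea_px
    if not (0 <= r < shape[0] and 0 <= c < shape[1]):
        raise ValueError(f"fovea {fovea_px} lies outside the {shape} raster")
    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    return GradingTemplate(
        fovea_px=(float(r), float(c)), scale_um_per_px=scale_um_per_px, shape=tuple(shape)
    )


def quantify(drusen: DrusenMap, template: GradingTemplate) -> SubfieldMetrics:
    """Accumulate per-subfield number, total diameter and total area.

    Each druse goes entirely to the subfield containing its centroid;
    drusen centered outside the 6000 µm circle are excluded from every
    field.
    """
    if drusen.labels.shape != template.shape:
        raise ValueError("drusen map and template are not congruent")
    if abs(drusen.scale_um_per_px - template.scale_um_per_px) > 1e-12:
        raise ValueError("drusen map and template scales differ")
    table = pd.DataFrame(
        0.0, index=list(FIELDS), columns=["number", "diameter_um", "area_um2"]
    )
    for _, comp in drusen.components.iterrows():
        sf = template.subfield_of(comp["centroid_row"], comp["centroid_col"])
        if sf == "outside":
            continue
        table.loc[sf, "number"] += 1
        table.loc[sf, "diameter_um"] += comp["diameter_um"]
        table.loc[sf, "area_um2"] += comp["area_um2"]
    table.loc["all"] = table.loc[["inner", "middle", "outer"]].sum(axis=0)
    return SubfieldMetrics(table=table, scale_um_per_px=template.scale_um_per_px)
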