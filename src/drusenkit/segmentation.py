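"""Drusen delineation inside operator-supervised regions.

Segmentation runs on the leveled image: one global Otsu threshold over the
effective region of interest (drusen ROI minus reticular-pseudodrusen and
geographic-atrophy exclusions), 8-connected components above the threshold,
and a small-component floor. Each druse is measured in physical units and
classed by equivalent diameter into the conventional bands: small < 63 µm,
intermediate 63–125 µm, large ≥ 125 µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .core import FundusImage
from .leveling import DegenerateHistogramError

__all__ = [
    "AnnotationSet",
    "DrusenMap",
    "segment_drusen",
    "equivalent_diameter",
    "classify_druse_size",
    "SIZE_CLASS_BOUNDS_UM",
]

#: Half-open size-class boundaries in µm: [0, 63) small, [63, 125) intermediate.
SIZE_CLASS_BOUNDS_UM = (63.0, 125.0)


@dataclass
class AnnotationSet:
    """Operator supervision for one image.

    ``roi`` marks areas containing drusen (initializes the segmentation);
    ``reticular`` encloses reticular-pseudodrusen regions excluded from
    drusen measurements; ``ga`` masks geographic atrophy. Exclusions may
    overlap the ROI; excluded pixels are never labeled.
    """

    roi: np.ndarray
    reticular: np.ndarray | None = None
    ga: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.roi = np.asarray(self.roi, dtype=bool)
        for name in ("reticular", "ga"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != self.roi.shape:
                    raise ValueError(f"{name} mask shape does not match roi")
                setattr(self, name, m)

    @classmethod
    def from_polygons(
        cls,
        shape: tuple[int, int],
        roi: list[tuple[float, float]],
        reticular: list[tuple[float, float]] | None = None,
        ga: list[tuple[float, float]] | None = None,
    ) -> "AnnotationSet":
        """Build masks from (row, col) polygon vertex lists."""
        mk = lambda poly: polygon2mask(shape, np.asarray(poly, dtype=float))
        return cls(
            roi=mk(roi),
            reticular=mk(reticular) if reticular else None,
            ga=mk(ga) if ga else None,
        )

    def effective_roi(self) -> np.ndarray:
        eff = self.roi.copy()
        if self.reticular is not None:
            eff &= ~self.reticular
        if self.ga is not None:
            eff &= ~self.ga
        return eff


@dataclass
class DrusenMap:
    """Labeled druse components with per-component measurements.

    ``labels`` is the component raster (0 = background); ``components`` has
    one row per druse: ``label, n_px, area_um2, diameter_um, centroid_row,
    centroid_col, size_class``.
    """

    labels: np.ndarray
    components: pd.DataFrame
    scale_um_per_px: float
    threshold: float | None = None
    fovea_px: tuple[float, float] | None = None

    @property
    def n_drusen(self) -> int:
        return len(self.components)

    def foreground(self) -> np.ndarray:
        return self.labels > 0

    @property
    def total_area_um2(self) -> float:
        return float(self.components["area_um2"].sum())


def equivalent_diameter(area_um2: float) -> float:
    """Diameter (µm) of the circle with the same area: ``2·sqrt(area/π)``."""
    if area_um2 < 0:
        raise ValueError("area must be non-negative")
    return float(2.0 * np.sqrt(area_um2 / np.pi))


def classify_druse_size(diameter_um: float) -> str:
    """Size class by equivalent diameter: small / intermediate / large."""
    if diameter_um < 0:
        raise ValueError("diameter must be non-negative")
    lo, hi = SIZE_CLASS_BOUNDS_UM
    if diameter_um < lo:
        return "small"
    if diameter_um < hi:
        return "intermediate"
    return "large"


def segment_drusen(
    leveled: FundusImage,
    annotations: AnnotationSet,
    min_druse_px: int = 4,
    smooth_sigma: float = 1.0,
) -> DrusenMap:
    """Threshold and label drusen within the supervised region.

    The leveled image is first lightly smoothed (``smooth_sigma`` px, the
    enhancement step; 0 disables it), then one Otsu threshold is computed
    from the intensities inside the effective ROI (ROI minus exclusions);
    pixels strictly above it form 8-connected components, and components
    smaller than ``min_druse_px`` are dropped. Pixels inside exclusion
    regions are never labeled.
    """
    if annotations.roi.shape != leveled.shape:
        raise ValueError("annotation masks do not match image shape")
    eff = annotations.effective_roi()
    if not eff.any():
        raise ValueError("effective ROI is empty after subtracting exclusions")
    data = gaussian_filter(leveled.data, smooth_sigma) if smooth_sigma > 0 else leveled.data
    values = data[eff]
    if np.unique(values).size < 2:
        raise DegenerateHistogramError("leveled image constant within effective ROI")
    thr = float(threshold_otsu(values))
    fg = (data > thr) & eff
    labels = label(fg, connectivity=2)

    scale = leveled.scale_um_per_px
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=np.int64)
    nxt = 1
    for p in regionprops(labels):
        if p.num_pixels < min_druse_px:
            continue
        keep[p.label] = nxt
        area = p.num_pixels * scale * scale
        diam = equivalent_diameter(area)
        rows.append(
            {
                "label": nxt,
                "n_px": int(p.num_pixels),
                "area_um2": area,
                "diameter_um": diam,
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
                "size_class": classify_druse_size(diam),
            }
        )
        nxt += 1
    relabeled = keep[labels]
    components = pd.DataFrame(
        rows,
        columns=[
            "label",
            "n_px",
            "area_um2",
            "diameter_um",
            "centroid_row",
            "centroid_col",
            "size_class",
        ],
    )
    return DrusenMap(
        labels=relabeled,
        components=components,
        scale_um_per_px=scale,
        threshold=thr,
        fovea_px=leveled.fovea_px,
    )
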