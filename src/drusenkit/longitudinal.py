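"""Per-subject remodeling (D1−D0) and drusen→GA overlap accounting.

Remodeling of each drusen characteristic (number, total diameter, total
area) in each subfield is the final-visit value minus the baseline value,
computed on registered images so the subfields coincide. For eyes that
developed geographic atrophy by the final visit, the baseline drusen mask
(registered into the final frame) is intersected with the final GA mask to
account for how much GA arose from former drusen and how much baseline
drusen converted to GA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantification import FIELDS, SubfieldMetrics

__all__ = ["RemodelingRecord", "GAOverlapResult", "remodel", "ga_overlap", "cohort_ga_summary"]


@dataclass(frozen=True)
class RemodelingRecord:
    """D1−D0 differences per metric per subfield.

    ``delta`` is indexed like a metrics table (inner, middle, outer, all ×
    number, diameter_um, area_um2) and equals ``final.table − baseline.table``
    cell by cell.
    """

    baseline: SubfieldMetrics
    final: SubfieldMetrics
    delta: pd.DataFrame

    def value(self, metric: str, subfield: str) -> float:
        col = {"number": "number", "diameter": "diameter_um", "area": "area_um2"}[metric]
        return float(self.delta.loc[subfield, col])

    def to_row(self, prefix: str = "delta") -> dict[str, float]:
        """Flatten to ``{prefix}_{metric}_{subfield}`` keys for a cohort table."""
        out = {}
        for metric, col in [("number", "number"), ("diameter", "diameter_um"), ("area", "area_um2")]:
            for sf in FIELDS:
                out[f"{prefix}_{metric}_{sf}"] = float(self.delta.loc[sf, col])
        return out


def remodel(baseline: SubfieldMetrics, final: SubfieldMetrics) -> RemodelingRecord:
    """Elementwise D1 − D0 across all 12 cells."""
    if abs(baseline.scale_um_per_px - final.scale_um_per_px) > 1e-12:
        raise ValueError("baseline and final metrics use different scales")
    delta = final.table - baseline.table
    return RemodelingRecord(baseline=baseline, final=final, delta=delta)


@dataclass(frozen=True)
class GAOverlapResult:
    """Pixel accounting of baseline drusen that became geographic atrophy.

    Percents are reported both unrounded and rounded to the nearest integer.
    ``pct_of_ga`` is None (missing) when the GA area is zero.
    """

    drusen_px: int
    ga_px: int
    overlap_px: int
    pct_of_ga: float | None
    pct_of_drusen: float | None
    pct_of_ga_rounded: int | None
    pct_of_drusen_rounded: int | None


def ga_overlap(drusen_baseline: np.ndarray, ga_final: np.ndarray) -> GAOverlapResult:
    """Intersect a registered baseline drusen mask with the final GA mask.

    Returns the overlap pixel area, the percent of the GA area that was
    formerly drusen (100·overlap/GA) and the percent of baseline drusen
    that converted to GA (100·overlap/drusen).
    """
    d = np.asarray(drusen_baseline, dtype=bool)
    g = np.asarray(ga_final, dtype=bool)
    if d.shape != g.shape:
        raise ValueError("masks must be congruent")
    drusen_px = int(d.sum())
    ga_px = int(g.sum())
    overlap = int((d & g).sum())
    pct_ga = 100.0 * overlap / ga_px if ga_px > 0 else None
    pct_dr = 100.0 * overlap / drusen_px if drusen_px > 0 else None
    rnd = lambda v: int(round(v)) if v is not None else None
    return GAOverlapResult(
        drusen_px=drusen_px,
        ga_px=ga_px,
        overlap_px=overlap,
        pct_of_ga=pct_ga,
        pct_of_drusen=pct_dr,
        pct_of_ga_rounded=rnd(pct_ga),
        pct_of_drusen_rounded=rnd(pct_dr),
    )


def cohort_ga_summary(results: list[GAOverlapResult]) -> dict[str, float | int | None]:
    """Cohort averages of the GA accounting.

    The headline percents are means of the per-subject percentages
    (subjects whose denominator is zero are excluded from that mean);
    pooled-pixel ratios are also reported for comparison.
    """
    if not results:
        raise ValueError("need at least one GA overlap result")
    drusen = np.array([r.drusen_px for r in results], dtype=float)
    ga = np.array([r.ga_px for r in results], dtype=float)
    overlap = np.array([r.overlap_px for r in results], dtype=float)
    pct_ga = [r.pct_of_ga for r in results if r.pct_of_ga is not None]
    pct_dr = [r.pct_of_drusen for r in results if r.pct_of_drusen is not None]
    return {
        "n_subjects": len(results),
        "mean_drusen_px": float(drusen.mean()),
        "mean_ga_px": float(ga.mean()),
        "mean_pct_of_ga": float(np.mean(pct_ga)) if pct_ga else None,
        "mean_pct_of_drusen": float(np.mean(pct_dr)) if pct_dr else None,
        "pooled_pct_of_ga": float(100.0 * overlap.sum() / ga.sum()) if ga.sum() else None,
        "pooled_pct_of_drusen": float(100.0 * overlap.sum() / drusen.sum())
        if drusen.sum()
        else None,
    }
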