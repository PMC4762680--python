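"""Ground-truthed synthetic macular images and trial-shaped cohorts.

Every downstream stage (leveling, segmentation, registration, remodeling,
statistics) is exercised against data from this module, so each generated
object carries its exact ground truth.

The photometric model of a druse is an additive elliptical super-Gaussian
bump: ``contrast(p) = A · exp(-ln 2 · ρ(p)⁴)`` where ``ρ`` is the
elliptical radius normalized by the semi-axes. The profile has the gentle
plateau and steep shoulder of a soft drusen deposit, and it equals half
its peak exactly on the stated ellipse, so the "true" druse support — the
half-maximum set — is the ellipse itself and its analytic area is
``π·a·b``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FundusImage, quadratic_basis

__all__ = [
    "Druse",
    "GAPatch",
    "VisitTransform",
    "DrusenChanges",
    "SimImageParams",
    "GroundTruth",
    "generate_fundus_pair",
    "CohortParams",
    "generate_cohort",
    "default_segmentation_suite",
    "default_registration_suite",
    "operator_roi",
    "SUBFIELDS",
    "METRICS",
]

SUBFIELDS = ("inner", "middle", "outer")
METRICS = ("number", "diameter", "area")


@dataclass(frozen=True)
class Druse:
    """One simulated druse: an additive plateau-shaped elliptical bump."""

    center_px: tuple[float, float]  # (row, col)
    semi_axes_um: tuple[float, float]
    peak_contrast: float
    angle_deg: float = 0.0

    def validate(self) -> None:
        if min(self.semi_axes_um) <= 0:
            raise ValueError(f"druse semi-axes must be positive, got {self.semi_axes_um}")

    @property
    def area_um2(self) -> float:
        """Analytic half-maximum support area: π·a·b."""
        return float(np.pi * self.semi_axes_um[0] * self.semi_axes_um[1])


@dataclass(frozen=True)
class GAPatch:
    """A circular geographic-atrophy patch added at the final visit."""

    center_px: tuple[float, float]
    radius_um: float
    contrast: float = 40.0


@dataclass(frozen=True)
class VisitTransform:
    """Similarity map from the baseline frame to the final frame.

    ``p_final = scale · R(rotation) · (p − center) + center + translation``
    with ``center`` the raster center, coordinates in (row, col) pixels.
    """

    rotation_deg: float = 0.0
    translation_px: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def validate(self) -> None:
        if self.scale == 0:
            raise ValueError("visit transform scale must be nonzero (invertible)")

    def matrix_rc(self, shape: tuple[int, int]) -> np.ndarray:
        """Homogeneous 3×3 matrix acting on (row, col, 1) column vectors."""
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lin = self.scale * rot
        ctr = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
        t = ctr + np.asarray(self.translation_px, dtype=float) - lin @ ctr
        m = np.eye(3)
        m[:2, :2] = lin
        m[:2, 2] = t
        return m

    def matrix_xy(self, shape: tuple[int, int]) -> np.ndarray:
        """Same map expressed on (x, y, 1) = (col, row, 1) vectors."""
        m = self.matrix_rc(shape)
        out = np.eye(3)
        out[:2, :2] = m[:2, :2][::-1, ::-1]
        out[:2, 2] = m[:2, 2][::-1]
        return out


@dataclass(frozen=True)
class DrusenChanges:
    """Drusen remodeling between the two visits, by construction.

    ``removed`` indexes baseline drusen absent at the final visit; ``grown``
    maps baseline indices to a semi-axis scale factor (area scales with its
    square); ``added`` lists new drusen present only at the final visit
    (their centers are given in the baseline frame).
    """

    removed: tuple[int, ...] = ()
    grown: dict[int, float] = field(default_factory=dict)
    added: tuple[Druse, ...] = ()


@dataclass
class SimImageParams:
    """Full specification of one synthetic serial image pair."""

    shape: tuple[int, int] = (256, 256)
    scale_um_per_px: float = 30.0
    fovea_px: tuple[float, float] | None = None  # default: raster center
    # one 6-vector (constant, x, y, x², xy, y²) per concentric zone, inner first
    background_coeffs: tuple[tuple[float, ...], ...] = ((120.0, 0.0, 0.0, -15.0, 0.0, -10.0),)
    zone_radii_um: tuple[float, ...] = ()  # boundaries between zones, len = n_zones-1
    zone_blend_um: float = 300.0
    vignetting: float = 0.0  # multiplicative corner falloff fraction
    noise_sd: float = 2.0
    drusen: tuple[Druse, ...] = ()
    ga_patch: GAPatch | None = None
    reticular_polygon: tuple[tuple[float, float], ...] | None = None
    transform: VisitTransform = field(default_factory=VisitTransform)
    changes: DrusenChanges = field(default_factory=DrusenChanges)

    def validate(self) -> None:
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if len(self.zone_radii_um) != len(self.background_coeffs) - 1:
            raise ValueError("need one zone boundary fewer than zone coefficient sets")
        self.transform.validate()
        for d in self.drusen + tuple(self.changes.added):
            d.validate()
            self._check_inside(d)
        for idx in self.changes.removed:
            if not 0 <= idx < len(self.drusen):
                raise ValueError(f"removed index {idx} out of range")
        for idx, f in self.changes.grown.items():
            if not 0 <= idx < len(self.drusen):
                raise ValueError(f"grown index {idx} out of range")
            if f <= 0:
                raise ValueError("growth factor must be positive")

    def _check_inside(self, d: Druse) -> None:
        rmax = max(d.semi_axes_um) / self.scale_um_per_px
        r, c = d.center_px
        h, w = self.shape
        if not (rmax <= r <= h - 1 - rmax and rmax <= c <= w - 1 - rmax):
            raise ValueError(
                f"druse at {d.center_px} with semi-axes {d.semi_axes_um} µm "
                f"extends outside the {self.shape} raster at {self.scale_um_per_px} µm/px"
            )

    @property
    def fovea(self) -> tuple[float, float]:
        if self.fovea_px is not None:
            return self.fovea_px
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    def final_drusen(self) -> tuple[Druse, ...]:
        """Druse list at the final visit, in baseline-frame coordinates."""
        out = []
        for i, d in enumerate(self.drusen):
            if i in self.changes.removed:
                continue
            if i in self.changes.grown:
                f = self.changes.grown[i]
                d = dataclasses.replace(
                    d, semi_axes_um=(d.semi_axes_um[0] * f, d.semi_axes_um[1] * f)
                )
            out.append(d)
        out.extend(self.changes.added)
        return tuple(out)


@dataclass
class GroundTruth:
    """Exact per-pair truth for every downstream contract."""

    drusen_mask_baseline: np.ndarray  # bool, baseline frame
    drusen_mask_final: np.ndarray  # bool, final frame
    background_baseline: np.ndarray
    background_final: np.ndarray
    ga_mask_final: np.ndarray  # bool, final frame (all False when absent)
    transform_xy: np.ndarray  # 3×3 baseline→final map on (x, y, 1)
    druse_areas_baseline_um2: tuple[float, ...]
    druse_areas_final_um2: tuple[float, ...]

    def __post_init__(self) -> None:
        for m in (self.drusen_mask_baseline, self.drusen_mask_final, self.ga_mask_final):
            if m.dtype != bool:
                raise ValueError("ground-truth masks must be boolean")
        if self.drusen_mask_baseline.shape != self.drusen_mask_final.shape:
            raise ValueError("visit masks must be congruent")


_LN2 = float(np.log(2.0))


def _druse_field(rr: np.ndarray, cc: np.ndarray, drusen: tuple[Druse, ...], scale: float):
    """Additive druse contrast and half-maximum support on coordinate grids."""
    bump = np.zeros_like(rr, dtype=float)
    support = np.zeros_like(rr, dtype=bool)
    for d in drusen:
        a_px = d.semi_axes_um[0] / scale
        b_px = d.semi_axes_um[1] / scale
        th = np.deg2rad(d.angle_deg)
        dr = rr - d.center_px[0]
        dc = cc - d.center_px[1]
        u = (np.cos(th) * dr + np.sin(th) * dc) / a_px
        v = (-np.sin(th) * dr + np.cos(th) * dc) / b_px
        rho2 = u * u + v * v
        bump += d.peak_contrast * np.exp(-_LN2 * rho2 * rho2)
        support |= rho2 <= 1.0
    return bump, support


def _background(rr, cc, params: SimImageParams) -> np.ndarray:
    """Smooth zoned-quadratic background with optional vignetting."""
    h, w = params.shape
    fovea = params.fovea
    half_span = max(h, w) / 2.0
    basis = quadratic_basis(rr, cc, fovea, half_span)
    surfaces = [basis @ np.asarray(cf, dtype=float) for cf in params.background_coeffs]
    if len(surfaces) == 1:
        bg = surfaces[0]
    else:
        d_um = np.hypot(rr - fovea[0], cc - fovea[1]) * params.scale_um_per_px
        bg = surfaces[0].copy()
        for b_um, nxt in zip(params.zone_radii_um, surfaces[1:]):
            t = np.clip((d_um - (b_um - params.zone_blend_um / 2)) / params.zone_blend_um, 0, 1)
            wgt = t * t * (3 - 2 * t)  # cubic cross-fade
            bg = (1 - wgt) * bg + wgt * nxt
    if params.vignetting:
        ctr = ((h - 1) / 2.0, (w - 1) / 2.0)
        d2 = ((rr - ctr[0]) ** 2 + (cc - ctr[1]) ** 2) / (ctr[0] ** 2 + ctr[1] ** 2)
        bg = bg * (1.0 - params.vignetting * d2)
    return bg


def generate_fundus_pair(
    params: SimImageParams, seed: int
) -> tuple[FundusImage, FundusImage, GroundTruth]:
    """Render a registered serial image pair with exact ground truth.

    The baseline image is rendered on the pixel grid; the final image is the
    same scene viewed under ``params.transform`` with its own drusen list
    (``params.changes`` applied), GA patch, and independent pixel noise.
    Identical ``params`` and ``seed`` give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    h, w = params.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)

    bg0 = _background(rr, cc, params)
    bump0, mask0 = _druse_field(rr, cc, params.drusen, params.scale_um_per_px)
    img0 = bg0 + bump0
    if params.noise_sd > 0:
        img0 = img0 + rng.normal(0.0, params.noise_sd, size=(h, w))

    # final frame: pull scene coordinates back through the inverse transform
    m = params.transform.matrix_rc(params.shape)
    minv = np.linalg.inv(m)
    r0 = minv[0, 0] * rr + minv[0, 1] * cc + minv[0, 2]
    c0 = minv[1, 0] * rr + minv[1, 1] * cc + minv[1, 2]

    drusen1 = params.final_drusen()
    bg1 = _background(r0, c0, params)
    bump1, mask1 = _druse_field(r0, c0, drusen1, params.scale_um_per_px)
    img1 = bg1 + bump1
    ga_mask = np.zeros((h, w), dtype=bool)
    if params.ga_patch is not None:
        g = params.ga_patch
        d_um = np.hypot(r0 - g.center_px[0], c0 - g.center_px[1]) * params.scale_um_per_px
        ga_mask = d_um <= g.radius_um
        img1 = img1 + g.contrast * ga_mask
    if params.noise_sd > 0:
        img1 = img1 + rng.normal(0.0, params.noise_sd, size=(h, w))

    fovea0 = params.fovea
    f1 = m @ np.array([fovea0[0], fovea0[1], 1.0])
    fovea1 = (float(np.clip(f1[0], 0, h - 1)), float(np.clip(f1[1], 0, w - 1)))

    truth = GroundTruth(
        drusen_mask_baseline=mask0,
        drusen_mask_final=mask1,
        background_baseline=bg0,
        background_final=bg1,
        ga_mask_final=ga_mask,
        transform_xy=params.transform.matrix_xy(params.shape),
        druse_areas_baseline_um2=tuple(d.area_um2 for d in params.drusen),
        druse_areas_final_um2=tuple(d.area_um2 for d in drusen1),
    )
    baseline = FundusImage(img0, params.scale_um_per_px, fovea0)
    final = FundusImage(img1, params.scale_um_per_px, fovea1)
    return baseline, final, truth


def operator_roi(truth_mask: np.ndarray, radius_px: int = 10) -> np.ndarray:
    """Emulate the operator's supervision: a generous circling of the
    drusen-containing areas, built by dilating the true drusen support."""
    from skimage.morphology import dilation, disk

    return dilation(np.asarray(truth_mask, dtype=bool), disk(radius_px))


def default_segmentation_suite(
    n_images: int = 20,
    seed: int = 0,
    shape: tuple[int, int] = (160, 160),
    scale_um_per_px: float = 25.0,
    noise_sd: float = 3.0,
) -> list[tuple[SimImageParams, int]]:
    """The default segmentation-recovery conditions: 20 images of soft
    drusen on varying quadratic backgrounds with pixel noise.

    Drusen within one image share a base peak contrast (drawn per image
    from 20–40 intensity units, i.e. ≥ 3× the noise sd, with ±15%
    per-druse variation), emulating deposits of one material under one
    illumination. Returns (params, render seed) pairs.
    """
    rng = np.random.default_rng(seed)
    suite = []
    for _ in range(n_images):
        n_drusen = int(rng.integers(6, 12))
        base_contrast = rng.uniform(20.0, 40.0)
        margin = 14
        drusen = []
        for _ in range(n_drusen):
            a = rng.uniform(100, 250)
            r = rng.uniform(margin, shape[0] - 1 - margin)
            c = rng.uniform(margin, shape[1] - 1 - margin)
            drusen.append(
                Druse(
                    (r, c),
                    (a, a * rng.uniform(0.8, 1.25)),
                    base_contrast * rng.uniform(0.85, 1.15),
                )
            )
        coeffs = (
            float(rng.uniform(90, 140)),
            float(rng.uniform(-5, 5)),
            float(rng.uniform(-5, 5)),
            float(rng.uniform(-20, 0)),
            float(rng.uniform(-4, 4)),
            float(rng.uniform(-20, 0)),
        )
        params = SimImageParams(
            shape=shape,
            scale_um_per_px=scale_um_per_px,
            background_coeffs=(coeffs,),
            noise_sd=noise_sd,
            drusen=tuple(drusen),
        )
        suite.append((params, int(rng.integers(0, 2**31 - 1))))
    return suite


def default_registration_suite(
    n_pairs: int = 6,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    max_rotation_deg: float = 5.0,
    max_translation_px: float = 20.0,
    max_scale_dev: float = 0.05,
) -> list[tuple[SimImageParams, int]]:
    """The default registration-recovery conditions: serial pairs with
    rotation ≤ 5°, translation ≤ 20 px and scale within 5% of unity."""
    rng = np.random.default_rng(seed)
    suite = []
    for _ in range(n_pairs):
        drusen = []
        for _ in range(30):
            a = rng.uniform(60, 200)
            r = rng.uniform(30, shape[0] - 31)
            c = rng.uniform(30, shape[1] - 31)
            drusen.append(Druse((r, c), (a, a * rng.uniform(0.7, 1.3)), rng.uniform(20, 50)))
        transform = VisitTransform(
            rotation_deg=float(rng.uniform(-max_rotation_deg, max_rotation_deg)),
            translation_px=(
                float(rng.uniform(-max_translation_px, max_translation_px)),
                float(rng.uniform(-max_translation_px, max_translation_px)),
            ),
            scale=float(np.exp(rng.uniform(np.log(1 - max_scale_dev), np.log(1 + max_scale_dev)))),
        )
        params = SimImageParams(
            shape=shape,
            scale_um_per_px=30.0,
            noise_sd=2.0,
            drusen=tuple(drusen),
            transform=transform,
        )
        suite.append((params, int(rng.integers(0, 2**31 - 1))))
    return suite


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

# Baseline medians per metric × subfield, on the original scale. These emulate
# the pooled baseline drusen burden of a two-arm AMD cohort of this kind.
_BASELINE_MEDIAN = {
    ("number", "inner"): 6.0,
    ("number", "middle"): 34.0,
    ("number", "outer"): 44.0,
    ("diameter", "inner"): 156.0,
    ("diameter", "middle"): 388.0,
    ("diameter", "outer"): 432.0,
    ("area", "inner"): 60_000.0,
    ("area", "middle"): 370_000.0,
    ("area", "outer"): 460_000.0,
}

# Residual SDs of the 3-year change per metric × subfield (original scale).
_RESIDUAL_SD = {
    ("number", "inner"): 8.0,
    ("number", "middle"): 38.0,
    ("number", "outer"): 72.0,
    ("diameter", "inner"): 119.0,
    ("diameter", "middle"): 238.0,
    ("diameter", "outer"): 285.0,
    ("area", "inner"): 118_000.0,
    ("area", "middle"): 613_000.0,
    ("area", "outer"): 1_122_000.0,
}


@dataclass
class CohortParams:
    """Parameters of a simulated two-arm trial cohort.

    Defaults reproduce the demographic structure of a 167-subject AMD
    cohort (two arms allocated 1:1, mean age ~73.6 y, ~62% women) with
    drusen-remodeling effects concentrated in the inner subfield: an
    age–diameter correlation, a mean shift for women, a mean shift for the
    CFH TT genotype, and an (optionally zero) treatment shift applied to
    every cell.
    """

    n: int = 167
    allocation: float = 0.5  # probability of assignment to the treated arm
    age_mean: float = 73.6
    age_sd: float = 6.8
    prop_female: float = 0.617
    prop_smoker: float = 0.431
    cfh_freqs: tuple[float, float, float] = (0.29, 0.47, 0.24)  # CC, CT, TT
    arms2_freqs: tuple[float, float, float] = (0.31, 0.46, 0.23)
    baseline_log_sd: float = 0.8
    age_diameter_corr: float = -0.17  # age vs inner-subfield diameter change
    gender_shift: float = -40.0  # µm, women vs men, inner diameter change
    cfh_tt_shift: float = 55.0  # µm, TT vs CC/CT, inner diameter change
    treatment_shift: float = 0.0  # added to every remodeling cell, treated arm
    residual_scale: float = 1.0  # multiplies all residual SDs
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs n >= 2")
        for name, p in [
            ("allocation", self.allocation),
            ("prop_female", self.prop_female),
            ("prop_smoker", self.prop_smoker),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name, f in [("cfh_freqs", self.cfh_freqs), ("arms2_freqs", self.arms2_freqs)]:
            if abs(sum(f) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if not -1 < self.age_diameter_corr < 1:
            raise ValueError("correlation must lie in (-1, 1)")
        if self.residual_scale < 0:
            raise ValueError("residual_scale must be non-negative")


_GENOTYPES = ("CC", "CT", "TT")


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a subject table with baseline and 3-year drusen metrics.

    Baseline metrics are drawn on the log scale around fixed medians and
    exponentiated (hence non-negative). The remodeling outcome of each cell
    is Gaussian residual noise plus the configured additive effects; the
    inner-subfield diameter change is built to carry the requested Pearson
    correlation with age. The ``all`` field is the sum of the three
    subfields, so field additivity holds exactly.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    arm = np.where(rng.random(n) < params.allocation, "treated", "placebo")
    age = rng.normal(params.age_mean, params.age_sd, n)
    gender = np.where(rng.random(n) < params.prop_female, "female", "male")
    smoking = np.where(rng.random(n) < params.prop_smoker, "ever", "never")
    cfh = rng.choice(_GENOTYPES, size=n, p=params.cfh_freqs)
    arms2 = rng.choice(_GENOTYPES, size=n, p=params.arms2_freqs)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "arm": arm,
            "age": age,
            "gender": gender,
            "smoking": smoking,
            "cfh": cfh,
            "arms2": arms2,
        }
    )

    z_age = (age - np.mean(age)) / (np.std(age) if np.std(age) > 0 else 1.0)
    is_f = (gender == "female").astype(float)
    is_tt = (cfh == "TT").astype(float)
    is_tr = (arm == "treated").astype(float)

    for m in METRICS:
        for s in SUBFIELDS:
            mu = np.log(_BASELINE_MEDIAN[(m, s)])
            base = np.exp(rng.normal(mu, params.baseline_log_sd, n))
            if m == "number":
                base = np.round(base)
            sd = _RESIDUAL_SD[(m, s)] * params.residual_scale
            eps = rng.standard_normal(n)
            if m == "diameter" and s == "inner":
                r = params.age_diameter_corr
                delta = sd * (r * z_age + np.sqrt(1 - r * r) * eps)
                delta = delta + params.gender_shift * is_f + params.cfh_tt_shift * is_tt
            else:
                delta = sd * eps
            delta = delta + params.treatment_shift * is_tr
            df[f"baseline_{m}_{s}"] = base
            df[f"delta_{m}_{s}"] = delta
            df[f"final_{m}_{s}"] = base + delta
    for m in METRICS:
        for kind in ("baseline", "delta", "final"):
            df[f"{kind}_{m}_all"] = sum(df[f"{kind}_{m}_{s}"] for s in SUBFIELDS)
    return df
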