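"""Serial fundus image registration.

Aligning the baseline and final photographs makes the foveae coincide, so a
single grading template can be placed on the registered stack and D1−D0
remodeling can be read off congruent subfields.

The similarity estimator searches rotation × isotropic scale on a coarse
grid; at each candidate the translation is resolved in closed form by
upsampled phase correlation and the candidate is scored by the normalized
cross-correlation of the aligned images. A Nelder–Mead polish over
(rotation, log-scale) then brings the estimate to sub-pixel landmark
accuracy. The whole procedure is deterministic. The affine family refines
the similarity solution with local block-matching correspondences fitted by
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from skimage.filters import window
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, ProjectiveTransform, warp as _sk_warp

from .core import FundusImage

__all__ = [
    "PlanarTransform",
    "RegistrationError",
    "estimate_transform",
    "warp",
    "manual_fovea_fallback",
    "mean_landmark_error",
]


class RegistrationError(RuntimeError):
    """Raised when automatic alignment cannot be trusted."""


@dataclass(frozen=True)
class PlanarTransform:
    """Homogeneous planar map from the moving frame into the fixed frame.

    ``matrix`` is 3×3 and acts on ``(x, y, 1)`` column vectors with
    ``(x, y) = (col, row)``, matching scikit-image's convention. Helper
    methods accept and return ``(row, col)`` points.
    """

    matrix: np.ndarray
    family: str = "similarity"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("matrix must be 3×3")
        if abs(np.linalg.det(m[:2, :2])) < 1e-12:
            raise ValueError("transform linear part is singular")
        if self.family not in ("similarity", "affine"):
            raise ValueError("family must be 'similarity' or 'affine'")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, family: str = "similarity") -> "PlanarTransform":
        return cls(np.eye(3), family)

    @classmethod
    def translation_rc(cls, d_row: float, d_col: float) -> "PlanarTransform":
        m = np.eye(3)
        m[0, 2] = d_col
        m[1, 2] = d_row
        return cls(m)

    @classmethod
    def similarity_about(
        cls,
        center_rc: tuple[float, float],
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        translation_rc: tuple[float, float] = (0.0, 0.0),
    ) -> "PlanarTransform":
        """Rotation+scale about a center, followed by a translation."""
        th = np.deg2rad(rotation_deg)
        lin = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        cx, cy = center_rc[1], center_rc[0]
        ctr = np.array([cx, cy])
        t = ctr + np.array([translation_rc[1], translation_rc[0]]) - lin @ ctr
        m = np.eye(3)
        m[:2, :2] = lin
        m[:2, 2] = t
        return cls(m)

    def apply_rc(self, points_rc: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        xy = np.column_stack([pts[:, 1], pts[:, 0], np.ones(len(pts))])
        out = (self.matrix @ xy.T).T
        out = out[:, :2] / out[:, 2:3]
        return np.column_stack([out[:, 1], out[:, 0]])

    def inverse(self) -> "PlanarTransform":
        return PlanarTransform(np.linalg.inv(self.matrix), self.family)

    def compose(self, inner: "PlanarTransform") -> "PlanarTransform":
        """The map ``self ∘ inner`` (apply ``inner`` first)."""
        fam = "affine" if "affine" in (self.family, inner.family) else "similarity"
        return PlanarTransform(self.matrix @ inner.matrix, fam)

    @property
    def rotation_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    @property
    def scale(self) -> float:
        return float(np.sqrt(abs(np.linalg.det(self.matrix[:2, :2]))))

    @property
    def translation(self) -> tuple[float, float]:
        """Translation part as ``(d_row, d_col)``."""
        return (float(self.matrix[1, 2]), float(self.matrix[0, 2]))


def mean_landmark_error(
    estimated: PlanarTransform, reference: PlanarTransform, points_rc: np.ndarray
) -> float:
    """Mean Euclidean distance (px) between the two maps over landmarks."""
    a = estimated.apply_rc(points_rc)
    b = reference.apply_rc(points_rc)
    return float(np.mean(np.hypot(a[:, 0] - b[:, 0], a[:, 1] - b[:, 1])))


def _prep(data: np.ndarray) -> np.ndarray:
    d = np.nan_to_num(np.asarray(data, dtype=float))
    d = d - d.mean()
    return d * window("hann", d.shape)


def _masked_ncc(a: np.ndarray, b: np.ndarray) -> float:
    valid = np.isfinite(a) & np.isfinite(b)
    if valid.sum() < 16:
        return 0.0
    av, bv = a[valid], b[valid]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    return float((av * bv).sum() / denom) if denom > 0 else 0.0


def _resolve_translation(
    fixed_prep: np.ndarray,
    fixed_data: np.ndarray,
    moving_data: np.ndarray,
    rot_deg: float,
    scale: float,
    center: tuple[float, float],
    upsample: int,
) -> tuple[PlanarTransform, float]:
    """Best transform at a fixed rotation/scale, and its alignment score."""
    base = PlanarTransform.similarity_about(center, rot_deg, scale)
    aligned = np.nan_to_num(warp(moving_data, base))
    shifts, _, _ = phase_cross_correlation(
        fixed_prep, _prep(aligned), upsample_factor=upsample, normalization="phase"
    )
    tform = PlanarTransform.translation_rc(shifts[0], shifts[1]).compose(base)
    return tform, _masked_ncc(warp(moving_data, tform), fixed_data)


def estimate_transform(
    moving: FundusImage,
    fixed: FundusImage,
    family: str = "similarity",
    rotation_range_deg: float = 6.0,
    scale_range: float = 0.06,
    min_correlation: float = 0.2,
) -> PlanarTransform:
    """Estimate the map taking ``moving`` into the ``fixed`` frame.

    Designed for serial macular photographs that differ by a modest
    similarity (rotation within a few degrees, translation within tens of
    pixels, near-unit scale). Rotation and scale are found by a coarse grid
    search (translation resolved by phase correlation at each candidate)
    followed by a Nelder–Mead polish. Raises :class:`RegistrationError`,
    suggesting :func:`manual_fovea_fallback`, when the aligned images
    correlate too poorly for the result to be trusted.
    """
    if family not in ("similarity", "affine"):
        raise ValueError("family must be 'similarity' or 'affine'")
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed rasters must share a shape")
    center = ((fixed.shape[0] - 1) / 2.0, (fixed.shape[1] - 1) / 2.0)
    fixed_prep = _prep(fixed.data)
    mov = np.nan_to_num(np.asarray(moving.data, dtype=float))

    best = (-np.inf, 0.0, 0.0)  # (score, rot, log-scale)
    rots = np.arange(-rotation_range_deg, rotation_range_deg + 1e-9, 1.0)
    logs = np.linspace(-scale_range, scale_range, 5) if scale_range > 0 else [0.0]
    for rot in rots:
        for ls in logs:
            _, score = _resolve_translation(
                fixed_prep, fixed.data, mov, rot, float(np.exp(ls)), center, upsample=4
            )
            if score > best[0]:
                best = (score, float(rot), float(ls))

    def objective(x: np.ndarray) -> float:
        _, score = _resolve_translation(
            fixed_prep, fixed.data, mov, x[0], float(np.exp(x[1])), center, upsample=20
        )
        return -score

    res = minimize(
        objective,
        x0=np.array([best[1], best[2]]),
        method="Nelder-mead",
        options={"xatol": 0.01, "fatol": 1e-6, "maxiter": 80},
    )
    rot, ls = res.x
    tform, _ = _resolve_translation(
        fixed_prep, fixed.data, mov, float(rot), float(np.exp(ls)), center, upsample=100
    )
    ncc = _masked_ncc(warp(moving.data, tform), fixed.data)
    if ncc < min_correlation:
        raise RegistrationError(
            f"aligned-image correlation {ncc:.2f} below {min_correlation}; "
            "consider manual_fovea_fallback with operator fovea coordinates"
        )
    if family == "affine":
        tform = _refine_affine(mov, fixed.data, tform)
    return tform


def _refine_affine(
    moving: np.ndarray, fixed: np.ndarray, init: PlanarTransform, grid: int = 4
) -> PlanarTransform:
    """Least-squares affine fit to block-matching correspondences."""
    aligned = np.nan_to_num(warp(moving, init, fixed.shape))
    h, w = fixed.shape
    bh, bw = h // grid, w // grid
    src, dst = [], []
    for i in range(grid):
        for j in range(grid):
            sl = (slice(i * bh, (i + 1) * bh), slice(j * bw, (j + 1) * bw))
            fb, mb = fixed[sl], aligned[sl]
            if fb.std() < 1e-9 or mb.std() < 1e-9:
                continue
            shifts, _, _ = phase_cross_correlation(
                _prep(fb), _prep(mb), upsample_factor=10, normalization=None
            )
            cy, cx = i * bh + bh / 2.0, j * bw + bw / 2.0
            src.append([cx, cy])
            dst.append([cx + shifts[1], cy + shifts[0]])
    if len(src) < 3:
        return PlanarTransform(init.matrix, "affine")
    at = AffineTransform()
    if not at.estimate(np.asarray(src), np.asarray(dst)):
        return PlanarTransform(init.matrix, "affine")
    return PlanarTransform(at.params, "affine").compose(
        PlanarTransform(init.matrix, "affine")
    )


def warp(
    raster: np.ndarray,
    transform: PlanarTransform,
    target_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Resample a raster from the moving frame into the fixed frame.

    Intensity rasters use bilinear interpolation with out-of-field pixels
    set to NaN (missing); boolean masks use nearest-neighbor so the output
    stays binary, with out-of-field pixels False.
    """
    arr = np.asarray(raster)
    target_shape = tuple(target_shape) if target_shape is not None else arr.shape
    inv = ProjectiveTransform(np.linalg.inv(transform.matrix))
    if arr.dtype == bool:
        out = _sk_warp(
            arr.astype(float), inv, output_shape=target_shape, order=0, cval=0.0,
            preserve_range=True,
        )
        return out > 0.5
    out = _sk_warp(
        arr.astype(float), inv, output_shape=target_shape, order=1, cval=np.nan,
        preserve_range=True,
    )
    return out


def manual_fovea_fallback(
    fovea_moving_rc: tuple[float, float], fovea_fixed_rc: tuple[float, float]
) -> PlanarTransform:
    """Pure translation aligning operator-marked fovea coordinates."""
    dr = fovea_fixed_rc[0] - fovea_moving_rc[0]
    dc = fovea_fixed_rc[1] - fovea_moving_rc[1]
    return PlanarTransform.translation_rc(dr, dc)
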