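"""Background leveling of macular images.

The illumination/reflectance background of a fundus photograph is smooth but
not globally quadratic, so it is modeled by quadratic polynomials fitted in
concentric zones around the fovea and cross-faded with a cubic interpolant in
blending bands between zones. Otsu's histogram threshold selects the
background pixels that feed the fit; subtracting the fitted surface (plus a
constant offset) "levels" the image so drusen become threshold-separable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core import FundusImage, quadratic_basis

__all__ = [
    "BackgroundModel",
    "select_background_pixels",
    "fit_background_model",
    "level_image",
    "level",
    "DegenerateHistogramError",
]


class DegenerateHistogramError(ValueError):
    """Raised when a region has too few distinct intensities to threshold."""


@dataclass
class BackgroundModel:
    """Zoned-quadratic background surface for one image.

    ``coefficients[i]`` are the 6 least-squares quadratic coefficients of
    zone ``i`` (inner to outer) in the normalized basis
    ``[1, x, y, x², xy, y²]`` centered on the fovea; ``surface`` is the
    blended full-field reconstruction in intensity units.
    """

    zone_radii_um: tuple[float, ...]  # outer boundary of each zone; last = field edge
    coefficients: tuple[np.ndarray, ...]
    blend_um: float
    surface: np.ndarray
    fovea_px: tuple[float, float]
    scale_um_per_px: float

    @property
    def n_zones(self) -> int:
        return len(self.coefficients)

    def max_neighbor_step(self) -> float:
        """Largest absolute intensity step between 4-neighbors of the surface."""
        s = self.surface
        return float(
            max(np.abs(np.diff(s, axis=0)).max(), np.abs(np.diff(s, axis=1)).max())
        )


def select_background_pixels(image: FundusImage, roi: np.ndarray) -> np.ndarray:
    """Select background-class pixels inside ``roi`` by Otsu's threshold.

    Returns the boolean mask of ROI pixels at or below the Otsu threshold
    computed from the ROI histogram (drusen are brighter than background,
    so the lower class is background). The result is a subset of ``roi``.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError("roi shape does not match image")
    if not roi.any():
        raise ValueError("roi is empty")
    values = image.data[roi]
    if np.unique(values).size < 2:
        raise DegenerateHistogramError(
            "constant intensity within roi: Otsu threshold undefined"
        )
    thr = threshold_otsu(values)
    return (image.data <= thr) & roi


def _zone_layout(
    image: FundusImage, n_zones: int, blend_frac: float
) -> tuple[tuple[float, ...], float, np.ndarray]:
    """Concentric equal-width annular zones about the fovea, covering the field."""
    d_um = image.distance_um()
    field_radius = float(d_um.max())
    radii = tuple(field_radius * (i + 1) / n_zones for i in range(n_zones))
    blend = blend_frac * field_radius
    return radii, blend, d_um


def fit_background_model(
    image: FundusImage,
    background_mask: np.ndarray,
    n_zones: int = 3,
    blend_frac: float = 0.1,
) -> BackgroundModel:
    """Fit the zoned-quadratic background over the selected pixels.

    Each concentric zone gets its own least-squares quadratic fitted over
    the background pixels it contains; adjacent zone surfaces are joined by
    a cubic cross-fade along the radial coordinate over a band of width
    ``blend_frac`` times the field radius, so the reconstructed surface is
    continuous.
    """
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != image.shape:
        raise ValueError("background mask shape does not match image")
    radii, blend, d_um = _zone_layout(image, n_zones, blend_frac)
    h, w = image.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    half_span = max(h, w) / 2.0
    basis_full = quadratic_basis(rr, cc, image.fovea_px, half_span)

    coeffs = []
    inner = 0.0
    for i, outer in enumerate(radii):
        in_zone = (d_um >= inner) & (d_um <= outer) & background_mask
        npx = int(in_zone.sum())
        if npx < 6:
            raise ValueError(
                f"zone {i} (radii {inner:.0f}-{outer:.0f} µm) has only {npx} "
                "background pixels; a quadratic needs at least 6"
            )
        a = basis_full[in_zone]
        b = image.data[in_zone]
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        coeffs.append(sol)
        inner = outer

    surfaces = [basis_full @ c for c in coeffs]
    surface = surfaces[0].copy()
    for boundary, nxt in zip(radii[:-1], surfaces[1:]):
        t = np.clip((d_um - (boundary - blend / 2)) / max(blend, 1e-9), 0.0, 1.0)
        wgt = t * t * (3 - 2 * t)  # cubic Hermite cross-fade in the radial coordinate
        surface = (1 - wgt) * surface + wgt * nxt
    if not np.all(np.isfinite(surface)):
        raise ValueError("background surface is not finite")
    return BackgroundModel(
        zone_radii_um=radii,
        coefficients=tuple(coeffs),
        blend_um=blend,
        surface=surface,
        fovea_px=image.fovea_px,
        scale_um_per_px=image.scale_um_per_px,
    )


def level_image(image: FundusImage, model: BackgroundModel) -> FundusImage:
    """Subtract the background surface, keeping the mean intensity.

    The output is ``image − surface + mean(surface)``; the constant offset
    keeps typical leveled intensities non-negative and preserves druse
    contrast exactly.
    """
    if model.surface.shape != image.shape:
        raise ValueError("model surface shape does not match image")
    offset = float(model.surface.mean())
    return image.with_data(image.data - model.surface + offset)


def level(
    image: FundusImage,
    roi: np.ndarray | None = None,
    n_zones: int = 3,
    blend_frac: float = 0.1,
    per_zone_selection: bool = True,
) -> tuple[FundusImage, BackgroundModel]:
    """Convenience one-call leveling: select, fit, subtract.

    With ``per_zone_selection`` the Otsu background selection runs within
    each annular zone separately, so a bright background dome near the
    fovea is not mistaken wholesale for foreground; with it off a single
    global threshold is used.
    """
    if roi is None:
        roi = np.ones(image.shape, dtype=bool)
    if per_zone_selection and n_zones > 1:
        radii, _, d_um = _zone_layout(image, n_zones, blend_frac)
        bg = np.zeros(image.shape, dtype=bool)
        inner = 0.0
        for outer in radii:
            zone_roi = (d_um >= inner) & (d_um <= outer) & roi
            if zone_roi.any():
                try:
                    bg |= select_background_pixels(image, zone_roi)
                except DegenerateHistogramError:
                    bg |= zone_roi  # flat zone: every pixel is background
            inner = outer
    else:
        bg = select_background_pixels(image, roi)
    model = fit_background_model(image, bg, n_zones=n_zones, blend_frac=blend_frac)
    return level_image(image, model), model
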