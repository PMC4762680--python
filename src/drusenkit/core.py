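"""Shared containers for calibrated macular images.

Pixel coordinates are 0-based ``(row, col)`` with pixel centers at integer
coordinates; physical distances are measured center-to-center and expressed
in micrometers via the image's ``scale_um_per_px``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["FundusImage", "quadratic_basis"]


@dataclass(frozen=True)
class FundusImage:
    """A calibrated 2-D macular intensity raster.

    Parameters
    ----------
    data : ndarray
        2-D float array of intensities. Color photographs are reduced to a
        single channel before analysis (see :meth:`from_rgb`).
    scale_um_per_px : float
        Physical size of one pixel in micrometers. Must be positive.
    fovea_px : tuple of float
        ``(row, col)`` location of the foveal center, in pixels. The
        grading template and the leveling zone layout are centered here.
    """

    data: np.ndarray
    scale_um_per_px: float
    fovea_px: tuple[float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"image data must be 2-D, got shape {data.shape}")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")
        r, c = self.fovea_px
        if not (0 <= r < data.shape[0] and 0 <= c < data.shape[1]):
            raise ValueError(
                f"fovea {self.fovea_px} lies outside the {data.shape} raster"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "fovea_px", (float(r), float(c)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @classmethod
    def from_rgb(
        cls,
        rgb: np.ndarray,
        scale_um_per_px: float,
        fovea_px: tuple[float, float],
        channel: int = 1,
    ) -> "FundusImage":
        """Build from an RGB raster, keeping one channel.

        The default is the green channel, which carries the drusen contrast
        of a red-free photograph.
        """
        rgb = np.asarray(rgb)
        if rgb.ndim != 3 or rgb.shape[2] < 3:
            raise ValueError("expected an (H, W, 3+) RGB array")
        return cls(rgb[:, :, channel].astype(float), scale_um_per_px, fovea_px)

    def with_data(self, data: np.ndarray) -> "FundusImage":
        """Return a copy carrying ``data`` with the same calibration."""
        return replace(self, data=np.asarray(data, dtype=float))

    def distance_um(self) -> np.ndarray:
        """Euclidean distance of every pixel from the fovea, in µm."""
        rr, cc = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        d_px = np.hypot(rr - self.fovea_px[0], cc - self.fovea_px[1])
        return d_px * self.scale_um_per_px

    def to_uint8(self) -> np.ndarray:
        """Quantize to 8-bit for export (clipping to [0, 255])."""
        return np.clip(np.round(self.data), 0, 255).astype(np.uint8)


def quadratic_basis(rows: np.ndarray, cols: np.ndarray, center: tuple[float, float], half_span: float) -> np.ndarray:
    """Design matrix ``[1, x, y, x², xy, y²]`` in normalized coordinates.

    Coordinates are centered on ``center`` and divided by ``half_span`` so the
    normal equations stay well conditioned on large rasters.
    """
    if half_span <= 0:
        raise ValueError("half_span must be positive")
    y = (np.asarray(rows, dtype=float) - center[0]) / half_span
    x = (np.asarray(cols, dtype=float) - center[1]) / half_span
    return np.stack([np.ones_like(x), x, y, x * x, x * y, y * y], axis=-1)
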