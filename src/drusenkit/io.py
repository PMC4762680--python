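"""Reading and writing images, masks and tables in standard formats."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .core import FundusImage

__all__ = [
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "load_config_file",
    "save_config_file",
]


def load_image(
    path: str | Path,
    scale_um_per_px: float,
    fovea_px: tuple[float, float],
    channel: int = 1,
) -> FundusImage:
    """Read a PNG/TIFF/JPEG raster as a calibrated fundus image.

    Color images are reduced to one channel (default green, the red-free
    equivalent for drusen contrast).
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        return FundusImage.from_rgb(arr, scale_um_per_px, fovea_px, channel=channel)
    return FundusImage(arr.astype(float), scale_um_per_px, fovea_px)


def save_image(path: str | Path, image: FundusImage | np.ndarray, bits: int = 8) -> None:
    """Write an intensity raster quantized to 8- or 16-bit."""
    data = image.data if isinstance(image, FundusImage) else np.asarray(image, float)
    if bits == 8:
        out = np.clip(np.round(data), 0, 255).astype(np.uint8)
    elif bits == 16:
        out = np.clip(np.round(data * 256), 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    iio.imwrite(Path(path), out)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG mask as boolean."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 127


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def load_config_file(path: str | Path) -> dict:
    """Read a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config_file(path: str | Path, config: dict) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
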