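"""PNG/TIFF reading and writing.

Pixels are normalized to [0, 1] floats at read time: 8- and 16-bit integer
images are divided by their max code value; float images are used as-is
(clipped).  Grayscale images are stored single-channel; color written as
8-bit RGB.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .color import ColorImage

__all__ = ["read_gray", "read_color", "write_gray", "write_color"]


def _normalize(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / info.max
    return np.clip(arr.astype(float), 0.0, 1.0)


def read_gray(path: str | Path) -> np.ndarray:
    """Read an image as a 2-D [0, 1] array (RGB collapsed via channel mean)."""
    arr = iio.imread(path)
    arr = _normalize(np.asarray(arr))
    if arr.ndim == 3:
        arr = arr[:, :, :3].mean(axis=2)
    return arr


def read_color(path: str | Path) -> ColorImage:
    """Read an image as RGB in [0, 1]; alpha dropped, grayscale replicated."""
    arr = _normalize(np.asarray(iio.imread(path)))
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return ColorImage(arr[:, :, :3], space="RGB")


def write_gray(path: str | Path, img: np.ndarray, bits: int = 8) -> None:
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    if bits == 16:
        iio.imwrite(path, np.round(img * 65535).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(img * 255).astype(np.uint8))


def write_color(path: str | Path, img: ColorImage) -> None:
    if img.space != "RGB":
        raise ValueError("write_color expects an RGB image")
    data = np.clip(img.data, 0.0, 1.0)
    iio.imwrite(path, np.round(data * 255).astype(np.uint8))
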