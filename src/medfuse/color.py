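"""RGB <-> YIQ color handling for functional (pseudo-color) images.

Functional modalities (PET, SPECT, FDG, CBF) carry their clinical content in
chroma; fusion operates on the luma channel only.  The NTSC YIQ space
separates luminance Y from the two chroma axes I and Q, so a fused luma can
be re-inserted without disturbing the color coding of the source.

Two forward matrices are provided:

* ``"standard"`` (default) — the signed NTSC matrix whose I and Q rows each
  sum to zero, so achromatic pixels map to (Y, 0, 0).
* ``"paper-literal"`` — an all-positive variant seen in some typeset
  sources (minus signs dropped, 0.144 for the blue luma coefficient).  It
  does not separate chroma and exists only for comparison.

The inverse matrix is always computed numerically from the forward matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ColorImage",
    "YIQ_MATRICES",
    "rgb_to_yiq",
    "yiq_to_rgb",
    "replace_luma",
]

#: Forward RGB->YIQ matrices, rows (Y, I, Q).
YIQ_MATRICES: dict[str, np.ndarray] = {
    "standard": np.array(
        [
            [0.299, 0.587, 0.114],
            [0.596, -0.274, -0.322],
            [0.211, -0.523, 0.312],
        ]
    ),
    # All-positive variant with 0.144 in the luma row; kept verbatim.
    "paper-literal": np.array(
        [
            [0.299, 0.587, 0.144],
            [0.596, 0.274, 0.322],
            [0.211, 0.523, 0.312],
        ]
    ),
}


class ColorSpaceError(ValueError):
    """Raised on wrong channel count, wrong space tag, or a singular matrix."""


@dataclass
class ColorImage:
    """An H x W x 3 image tagged with its channel space.

    ``space`` is ``"RGB"`` (channels in [0, 1] after write-out clamping) or
    ``"YIQ"`` (unbounded chroma; never clamped while in YIQ).
    """

    data: np.ndarray
    space: str = "RGB"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ColorSpaceError(
                f"expected an HxWx3 array, got shape {self.data.shape}"
            )
        if self.space not in ("RGB", "YIQ"):
            raise ColorSpaceError(f"unknown color space tag {self.space!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def channel(self, i: int) -> np.ndarray:
        return self.data[:, :, i]


def _forward_matrix(matrix: str | np.ndarray) -> np.ndarray:
    if isinstance(matrix, str):
        try:
            return YIQ_MATRICES[matrix]
        except KeyError:
            raise ColorSpaceError(f"unknown matrix choice {matrix!r}") from None
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ColorSpaceError("conversion matrix must be 3x3")
    return m


def rgb_to_yiq(img: ColorImage, matrix: str | np.ndarray = "standard") -> ColorImage:
    """Convert an RGB image to YIQ by the per-pixel 3x3 linear map."""
    if img.space != "RGB":
        raise ColorSpaceError(f"rgb_to_yiq needs an RGB image, got {img.space}")
    m = _forward_matrix(matrix)
    out = img.data @ m.T
    return ColorImage(out, space="YIQ")


def yiq_to_rgb(
    img: ColorImage, matrix: str | np.ndarray = "standard", clamp: bool = True
) -> ColorImage:
    """Convert YIQ back to RGB with the exact inverse of the forward matrix.

    Out-of-gamut values are clamped to [0, 1] unless ``clamp=False`` (useful
    for checking chroma pass-through before gamut clipping).
    """
    if img.space != "YIQ":
        raise ColorSpaceError(f"yiq_to_rgb needs a YIQ image, got {img.space}")
    m = _forward_matrix(matrix)
    try:
        minv = np.linalg.inv(m)
    except np.linalg.LinAlgError as exc:
        raise ColorSpaceError(f"conversion matrix is singular: {m}") from exc
    out = img.data @ minv.T
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    return ColorImage(out, space="RGB")


def replace_luma(img: ColorImage, y: np.ndarray) -> ColorImage:
    """Return a YIQ image with channel 0 replaced by ``y``, chroma untouched."""
    if img.space != "YIQ":
        raise ColorSpaceError("replace_luma operates in YIQ space")
    y = np.asarray(y, dtype=float)
    if y.shape != img.shape:
        raise ColorSpaceError(
            f"luma shape {y.shape} does not match image shape {img.shape}"
        )
    out = img.data.copy()
    out[:, :, 0] = y
    return ColorImage(out, space="YIQ")
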