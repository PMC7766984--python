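"""Seeded synthetic phantoms: registered structural/functional pairs and a
grayscale training corpus.

Real paired brain slices (MRI plus PET/SPECT) cannot be redistributed, so
tests and examples run on phantoms: a structural image made of nested
ellipses (skull ring, tissue regions) with sharp edges and band-limited
texture, and a functional companion whose smooth activity blobs live
strictly inside the anatomy support and are rendered through a
black-blue-green-yellow-red flow colormap.  Both images of a pair derive
from one shared ellipse geometry, so they are registered by construction.

Everything is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .color import ColorImage

__all__ = [
    "PhantomGeometry",
    "PhantomPair",
    "make_geometry",
    "make_structural",
    "make_functional",
    "make_pair",
    "make_training_corpus",
    "flow_colormap",
]

MIN_SIZE = 32

#: anchors of the pseudo-color flow map: black -> blue -> green -> yellow -> red
_FLOW_ANCHORS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
_FLOW_COLORS = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 1.0, 0.0],
        [1.0, 1.0, 0.0],
        [1.0, 0.0, 0.0],
    ]
)


@dataclass
class PhantomGeometry:
    """Shared ellipse layout of one registered pair."""

    size: int
    head: tuple  # (cy, cx, ry, rx, angle)
    skull_scale: float
    inner: list = field(default_factory=list)  # (cy, cx, ry, rx, angle, value)
    seed: int = 0


@dataclass
class PhantomPair:
    structural: np.ndarray
    functional: ColorImage
    geometry: PhantomGeometry
    seed: int = 0


def _ellipse_mask(
    size: int, cy: float, cx: float, ry: float, rx: float, angle: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1.0)
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_geometry(size: int, seed: int) -> PhantomGeometry:
    """Draw the seeded ellipse layout used by both images of a pair."""
    if size < MIN_SIZE:
        raise ValueError(f"size must be >= {MIN_SIZE}, got {size}")
    rng = np.random.default_rng(seed)
    head = (
        0.5 + rng.uniform(-0.02, 0.02),
        0.5 + rng.uniform(-0.02, 0.02),
        rng.uniform(0.38, 0.44),
        rng.uniform(0.30, 0.36),
        rng.uniform(-0.3, 0.3),
    )
    inner = []
    for _ in range(rng.integers(3, 6)):
        inner.append(
            (
                head[0] + rng.uniform(-0.15, 0.15),
                head[1] + rng.uniform(-0.12, 0.12),
                rng.uniform(0.04, 0.14),
                rng.uniform(0.03, 0.11),
                rng.uniform(-np.pi, np.pi),
                rng.uniform(0.15, 0.85),
            )
        )
    return PhantomGeometry(
        size=size, head=head, skull_scale=0.90, inner=inner, seed=seed
    )


def brain_mask(geometry: PhantomGeometry) -> np.ndarray:
    """Support of the tissue region (inside the skull ring)."""
    cy, cx, ry, rx, ang = geometry.head
    s = geometry.skull_scale
    return _ellipse_mask(geometry.size, cy, cx, ry * s, rx * s, ang)


def make_structural(size: int, seed: int) -> np.ndarray:
    """Piecewise-constant nested-ellipse phantom with band-limited texture."""
    geo = make_geometry(size, seed)
    rng = np.random.default_rng(seed + 101)
    cy, cx, ry, rx, ang = geo.head
    img = np.zeros((size, size))
    outer = _ellipse_mask(size, cy, cx, ry, rx, ang)
    inner_sup = brain_mask(geo)
    img[outer] = 0.92  # skull ring
    img[inner_sup] = 0.35  # base tissue
    for e_cy, e_cx, e_ry, e_rx, e_ang, val in geo.inner:
        m = _ellipse_mask(size, e_cy, e_cx, e_ry, e_rx, e_ang) & inner_sup
        img[m] = val
    texture = gaussian_filter(rng.standard_normal((size, size)), sigma=1.2)
    img[inner_sup] += 0.08 * texture[inner_sup] / max(np.abs(texture).max(), 1e-12)
    return np.clip(img, 0.0, 1.0)


def flow_colormap(activity: np.ndarray) -> np.ndarray:
    """Map activity in [0, 1] through the black->blue->green->yellow->red ramp."""
    a = np.clip(np.asarray(activity, dtype=float), 0.0, 1.0)
    out = np.empty(a.shape + (3,))
    for c in range(3):
        out[..., c] = np.interp(a, _FLOW_ANCHORS, _FLOW_COLORS[:, c])
    return out


def make_functional(
    size: int,
    seed: int,
    geometry: PhantomGeometry,
    n_blobs: int | None = None,
) -> ColorImage:
    """Smooth activity blobs inside the anatomy, rendered in pseudo-color."""
    if geometry.size != size:
        raise ValueError(
            f"geometry was built for size {geometry.size}, requested {size}"
        )
    rng = np.random.default_rng(seed + 202)
    mask = brain_mask(geometry)
    if n_blobs is None:
        n_blobs = int(rng.integers(2, 6))
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1.0)
    activity = np.zeros((size, size))
    ys, xs = np.nonzero(mask)
    for _ in range(n_blobs):
        # sample blob centers on the tissue support
        idx = rng.integers(0, ys.size)
        by, bx = ys[idx] / (size - 1.0), xs[idx] / (size - 1.0)
        width = rng.uniform(0.05, 0.12)
        amp = rng.uniform(0.5, 1.0)
        activity += amp * np.exp(-((yy - by) ** 2 + (xx - bx) ** 2) / (2 * width**2))
    activity *= mask
    peak = activity.max()
    if peak > 0:
        activity /= peak
    return ColorImage(flow_colormap(activity), space="RGB")


def make_pair(size: int, seed: int) -> PhantomPair:
    """One registered structural/functional pair from a single seed."""
    geo = make_geometry(size, seed)
    return PhantomPair(
        structural=make_structural(size, seed),
        functional=make_functional(size, seed, geo),
        geometry=geo,
        seed=seed,
    )


def make_training_corpus(n: int, size: int = 64, seed: int = 0) -> list[np.ndarray]:
    """``n`` seeded grayscale images mixing ellipses, ramps and filtered noise.

    Each image is min-max stretched to [0, 1], which keeps histograms broad
    (corpus mean entropy comfortably above 4 bits at 256 levels) so the
    reconstruction loss sees a non-degenerate signal.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1.0)
    corpus = []
    for _ in range(n):
        theta = rng.uniform(0, 2 * np.pi)
        img = rng.uniform(0.3, 1.0) * (np.cos(theta) * xx + np.sin(theta) * yy)
        for _ in range(rng.integers(2, 6)):
            m = _ellipse_mask(
                size,
                rng.uniform(0.15, 0.85),
                rng.uniform(0.15, 0.85),
                rng.uniform(0.05, 0.3),
                rng.uniform(0.05, 0.3),
                rng.uniform(-np.pi, np.pi),
            )
            img[m] = rng.uniform(0, 1)
        noise = gaussian_filter(
            rng.standard_normal((size, size)), sigma=rng.uniform(1.0, 3.0)
        )
        img = img + rng.uniform(0.2, 0.5) * noise / max(np.abs(noise).max(), 1e-12)
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = (img - lo) / (hi - lo)
        corpus.append(img)
    return corpus
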