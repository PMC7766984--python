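"""Intuitionistic-fuzzy image enhancement (IFP).

Each source image is rescaled through a non-membership function

    nu_F(g) = (gmax - g) / (gmax - gmin)

built from its own observed extrema, raised to an exponent ``lam`` to give
the non-membership image ``nu = nu_F**lam``, and the enhanced image fed to
the encoder is its complement ``xi = 1 - nu``.  Large exponents (the grid
spans 200-800) push all but the darkest pixels toward 1, suppressing
low-intensity background while keeping the ordering of intensities: xi is
pointwise non-decreasing in g for fixed extrema.

The exponent is chosen per image by maximizing a fuzzy-entropy score

    E(lam) = mean over pixels of 2*mu*xi / (mu**2 + xi**2),

with the membership image ``mu = [(g - gmin)/(gmax - gmin)]**lam``.  The
score is 1 when membership and enhanced images agree everywhere and 0 when
membership vanishes; 0/0 pixels contribute 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "IFPResult",
    "non_membership",
    "ifs_images",
    "ifs_entropy",
    "select_lambda",
    "preprocess",
]

#: Exponent grid searched by default.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = (200, 300, 400, 500, 600, 700, 800)


class DegenerateImageWarning(UserWarning):
    """Emitted when a constant image cannot be fuzzified (gmax == gmin)."""


@dataclass
class IFPResult:
    """Outcome of the exponent search for one image."""

    enhanced: np.ndarray
    lambda_star: float
    entropy_by_lambda: dict[float, float] = field(default_factory=dict)
    degenerate: bool = False


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"expected a 2-D image of size >= 2x2, got {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def non_membership(img: np.ndarray) -> np.ndarray:
    """Linear non-membership nu_F(g) = (gmax - g)/(gmax - gmin) in [0, 1].

    A constant image is degenerate (division by zero); it yields nu == 0
    with a :class:`DegenerateImageWarning` instead of an exception, so a
    pipeline never dies mid-run on a blank slice.
    """
    img = _check_image(img)
    gmin, gmax = img.min(), img.max()
    if gmax == gmin:
        warnings.warn(
            "constant image: non-membership undefined, returning zeros",
            DegenerateImageWarning,
            stacklevel=2,
        )
        return np.zeros_like(img)
    return (gmax - img) / (gmax - gmin)


def ifs_images(
    img: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(nu, xi, mu)`` for exponent ``lam``.

    nu = nu_F**lam, xi = 1 - nu (the enhanced image), and
    mu = [(g - gmin)/(gmax - gmin)]**lam, the membership mirror of nu.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    nu_f = non_membership(img)
    nu = nu_f**lam
    xi = 1.0 - nu
    mu = (1.0 - nu_f) ** lam
    return nu, xi, mu


def ifs_entropy(img: np.ndarray, lam: float) -> float:
    """Fuzzy entropy in [0, 1]: mean of 2*mu*xi / (mu^2 + xi^2) over pixels."""
    _, xi, mu = ifs_images(img, lam)
    num = 2.0 * mu * xi
    den = mu * mu + xi * xi
    with np.errstate(invalid="ignore", divide="ignore"):
        term = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
    return float(term.mean())


def select_lambda(
    img: np.ndarray, grid: tuple[float, ...] | list[float] = DEFAULT_LAMBDA_GRID
) -> IFPResult:
    """Search ``grid`` exhaustively for the entropy-maximizing exponent.

    Ties break toward the smallest exponent so the result is deterministic.
    Constant images pass through unchanged with ``degenerate=True``.
    """
    img = _check_image(img)
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    if img.max() == img.min():
        warnings.warn(
            "constant image: IFP is a no-op", DegenerateImageWarning, stacklevel=2
        )
        return IFPResult(
            enhanced=img.copy(),
            lambda_star=grid[0],
            entropy_by_lambda={g: 0.0 for g in grid},
            degenerate=True,
        )
    entropy_by_lambda = {lam: ifs_entropy(img, lam) for lam in grid}
    best = max(sorted(entropy_by_lambda), key=lambda lam: entropy_by_lambda[lam])
    # max() keeps the first argmax of the sorted keys -> smallest lambda wins ties
    _, xi, _ = ifs_images(img, best)
    return IFPResult(enhanced=xi, lambda_star=best, entropy_by_lambda=entropy_by_lambda)


def preprocess(
    img: np.ndarray,
    grid: tuple[float, ...] | list[float] = DEFAULT_LAMBDA_GRID,
    enabled: bool = True,
) -> np.ndarray:
    """Enhanced image at the entropy-optimal exponent (identity if disabled)."""
    img = _check_image(img)
    if not enabled:
        return img
    return select_lambda(img, grid).enhanced
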