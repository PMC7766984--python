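"""Objective fusion-quality metrics.

For a triple (source ``a``, source ``b``, fused ``f``) of registered
grayscale images in [0, 1] this module computes the ten indices commonly
used to score medical image fusion:

========  ==========================================================
EN        Shannon entropy of the fused image's 256-bin histogram (bits)
CE        weighted symmetric histogram divergence fused-vs-sources
RMSE      weighted root-mean-square error fused-vs-sources
AG        average gradient (sharpness proxy)
SSIM      structural similarity, 11x11 Gaussian window
FMI       feature (gradient-image) mutual information, 64-bin
Qabf      saliency-weighted universal quality index (8x8 windows)
Qw        window-weighted variant (weights from window saliency)
Qe        edge-dependent variant (geometric mix with gradient images)
VIF       pixel-domain visual information fidelity, 4 scales
========  ==========================================================

Windowed quantities deliberately mirror naive sliding-window definitions so
they can be validated against brute-force loop implementations.  Windows
whose variance is numerically zero (below ``VAR_TOL``) are undefined for
the Q0 family and are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import correlate
from scipy.signal import fftconvolve

__all__ = [
    "MetricReport",
    "entropy_EN",
    "cross_entropy_CE",
    "rmse",
    "avg_gradient",
    "ssim",
    "q0",
    "qabf",
    "qw",
    "qe",
    "fmi",
    "mutual_information",
    "vif",
    "vif_fused",
    "evaluate_all",
    "gaussian_kernel",
    "gradient_magnitude",
]

#: windows with variance below this are treated as flat (Q0 undefined)
VAR_TOL = 1e-12

#: survey-derived weights for the fused-vs-source divergence (35/50, 15/50)
ETA_A = 0.7
ETA_B = 0.3

DEFAULT_PARAMS = {
    "hist_bins": 256,
    "eta_a": ETA_A,
    "eta_b": ETA_B,
    "rmse_wa": 0.5,
    "rmse_wb": 0.5,
    "ssim_win": 11,
    "ssim_sigma": 1.5,
    "ssim_c1": 0.01**2,
    "ssim_c2": 0.03**2,
    "q0_win": 8,
    "qe_alpha": 0.5,
    "fmi_bins": 64,
    "vif_scales": 4,
    "vif_sigma_n_sq": 2.0,
}


def _img(x: np.ndarray, min_dim: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {x.shape}")
    if min(x.shape) < min_dim:
        raise ValueError(f"image {x.shape} smaller than required {min_dim}")
    return x


def _same_shape(*imgs: np.ndarray) -> None:
    shapes = {i.shape for i in imgs}
    if len(shapes) > 1:
        raise ValueError(f"images must share a shape, got {shapes}")


# ---------------------------------------------------------------------------
# histogram-based metrics


def _hist_prob(x: np.ndarray, bins: int) -> np.ndarray:
    h, _ = np.histogram(x, bins=bins, range=(0.0, 1.0))
    return h / x.size


def entropy_EN(f: np.ndarray, bins: int = 256, literal: bool = False) -> float:
    """Shannon entropy (bits) of the gray-level histogram.

    ``literal=True`` evaluates the pixel-value form
    ``-sum f/(M*N) * log2(f/(M*N))`` instead (not a probability
    distribution; kept only for comparison).
    """
    f = _img(f)
    if literal:
        p = f / f.size
        nz = p > 0
        return float(-(p[nz] * np.log2(p[nz])).sum())
    p = _hist_prob(f, bins)
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def _sym_divergence(p: np.ndarray, q: np.ndarray, smooth: float = 1e-12) -> float:
    p = p + smooth
    q = q + smooth
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


def cross_entropy_CE(
    a: np.ndarray,
    b: np.ndarray,
    f: np.ndarray,
    eta_a: float = ETA_A,
    eta_b: float = ETA_B,
    bins: int = 256,
) -> float:
    """eta_a * D(hist a : hist f) + eta_b * D(hist b : hist f), D symmetric."""
    a, b, f = _img(a), _img(b), _img(f)
    _same_shape(a, b, f)
    pa, pb, pf = (_hist_prob(x, bins) for x in (a, b, f))
    return eta_a * _sym_divergence(pa, pf) + eta_b * _sym_divergence(pb, pf)


def rmse(
    a: np.ndarray,
    b: np.ndarray,
    f: np.ndarray,
    wa: float = 0.5,
    wb: float = 0.5,
) -> float:
    """Weighted per-source root-mean-square error of the fused image."""
    a, b, f = _img(a), _img(b), _img(f)
    _same_shape(a, b, f)
    r_af = np.sqrt(np.mean((a - f) ** 2))
    r_bf = np.sqrt(np.mean((b - f) ** 2))
    return float(wa * r_af + wb * r_bf)


def avg_gradient(f: np.ndarray) -> float:
    """Mean of sqrt((dx^2 + dy^2)/2) with forward differences, boundary excluded."""
    f = _img(f, min_dim=2)
    dx = f[:-1, :-1] - f[1:, :-1]
    dy = f[:-1, :-1] - f[:-1, 1:]
    return float(np.mean(np.sqrt((dx**2 + dy**2) / 2.0)))


# ---------------------------------------------------------------------------
# SSIM


def gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Normalized 2-D Gaussian window."""
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim_stats(
    x: np.ndarray, y: np.ndarray, kernel: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Gaussian-window local stats over fully-interior (valid) windows.

    Accepts 2-D images or batches ``[B, H, W]``; returns
    ``(mu_x, mu_y, var_x, var_y, cov_xy)`` maps.
    """
    k = kernel if x.ndim == 2 else kernel[None]
    mux = fftconvolve(x, k, mode="valid")
    muy = fftconvolve(y, k, mode="valid")
    vx = fftconvolve(x * x, k, mode="valid") - mux * mux
    vy = fftconvolve(y * y, k, mode="valid") - muy * muy
    cxy = fftconvolve(x * y, k, mode="valid") - mux * muy
    return mux, muy, vx, vy, cxy


def ssim_map(
    x: np.ndarray,
    y: np.ndarray,
    kernel: np.ndarray,
    c1: float = 0.01**2,
    c2: float = 0.03**2,
) -> np.ndarray:
    """Per-window SSIM (product form with c3 = c2/2, dynamic range 1)."""
    mux, muy, vx, vy, cxy = ssim_stats(x, y, kernel)
    return ((2 * mux * muy + c1) * (2 * cxy + c2)) / (
        (mux**2 + muy**2 + c1) * (vx + vy + c2)
    )


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    win_size: int = 11,
    sigma: float = 1.5,
    c1: float = 0.01**2,
    c2: float = 0.03**2,
) -> float:
    """Mean local SSIM over an 11x11 Gaussian window (sigma 1.5)."""
    x, y = _img(x, win_size), _img(y, win_size)
    _same_shape(x, y)
    return float(np.mean(ssim_map(x, y, gaussian_kernel(win_size, sigma), c1, c2)))


# ---------------------------------------------------------------------------
# Q0 family (universal image quality index and fusion extensions)


def _window_stats(a: np.ndarray, win: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window (step 1) mean and population variance maps."""
    w = sliding_window_view(a, (win, win))
    mu = w.mean(axis=(-1, -2))
    var = (w * w).mean(axis=(-1, -2)) - mu * mu
    return mu, var


def _q0_map(
    a: np.ndarray, b: np.ndarray, win: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window Q0 values and a validity mask (both windows non-flat)."""
    wa = sliding_window_view(a, (win, win))
    wb = sliding_window_view(b, (win, win))
    mua = wa.mean(axis=(-1, -2))
    mub = wb.mean(axis=(-1, -2))
    va = (wa * wa).mean(axis=(-1, -2)) - mua * mua
    vb = (wb * wb).mean(axis=(-1, -2)) - mub * mub
    cab = (wa * wb).mean(axis=(-1, -2)) - mua * mub
    valid = (va > VAR_TOL) & (vb > VAR_TOL)
    den = (va + vb) * (mua * mua + mub * mub)
    q = np.zeros_like(den)
    np.divide(4.0 * cab * mua * mub, den, out=q, where=valid & (den > 0))
    return q, valid


def q0(a: np.ndarray, b: np.ndarray, win: int = 8) -> float:
    """Universal image quality index: mean Q0 over valid sliding windows."""
    a, b = _img(a, win), _img(b, win)
    _same_shape(a, b)
    qmap, valid = _q0_map(a, b, win)
    if not valid.any():
        return float("nan")
    return float(qmap[valid].mean())


def _qabf_terms(
    a: np.ndarray, b: np.ndarray, f: np.ndarray, win: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window combined quality, saliency max(s_a, s_b), validity mask."""
    qaf, vaf = _q0_map(a, f, win)
    qbf, vbf = _q0_map(b, f, win)
    _, sa = _window_stats(a, win)
    _, sb = _window_stats(b, win)
    tot = sa + sb
    lam = np.where(tot > 0, np.divide(sa, np.where(tot > 0, tot, 1.0)), 0.5)
    combined = lam * qaf + (1.0 - lam) * qbf
    return combined, np.maximum(sa, sb), vaf & vbf


def qabf(a: np.ndarray, b: np.ndarray, f: np.ndarray, win: int = 8) -> float:
    """Mean over windows of lam*Q0(a,f) + (1-lam)*Q0(b,f), lam from saliency."""
    a, b, f = _img(a, win), _img(b, win), _img(f, win)
    _same_shape(a, b, f)
    combined, _, valid = _qabf_terms(a, b, f, win)
    if not valid.any():
        return float("nan")
    return float(combined[valid].mean())


def qw(a: np.ndarray, b: np.ndarray, f: np.ndarray, win: int = 8) -> float:
    """Saliency-weighted quality: windows with larger max-variance count more."""
    a, b, f = _img(a, win), _img(b, win), _img(f, win)
    _same_shape(a, b, f)
    combined, c_w, valid = _qabf_terms(a, b, f, win)
    if not valid.any():
        return float("nan")
    c = c_w[valid]
    total = c.sum()
    if total <= 0:
        weights = np.full(c.shape, 1.0 / c.size)
    else:
        weights = c / total
    return float((weights * combined[valid]).sum())


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """Euclidean norm of the central-difference gradient images."""
    gy, gx = np.gradient(np.asarray(img, dtype=float))
    return np.sqrt(gx**2 + gy**2)


def qe(
    a: np.ndarray,
    b: np.ndarray,
    f: np.ndarray,
    alpha_edge: float = 0.5,
    win: int = 8,
) -> float:
    """Edge-dependent quality: Qw^(1-alpha) on images times Qw^alpha on edges.

    Negative Qw values are floored at 0 before exponentiation; exact
    ``alpha_edge`` of 0 or 1 collapses to the corresponding Qw.
    """
    qw_img = qw(a, b, f, win)
    if alpha_edge == 0.0:
        return qw_img
    qw_edge = qw(
        gradient_magnitude(a), gradient_magnitude(b), gradient_magnitude(f), win
    )
    if alpha_edge == 1.0:
        return qw_edge
    return float(
        max(qw_img, 0.0) ** (1.0 - alpha_edge) * max(qw_edge, 0.0) ** alpha_edge
    )


# ---------------------------------------------------------------------------
# feature mutual information


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 64) -> float:
    """MI in bits from a joint histogram over each image's own value range."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.min() == x.max() or y.min() == y.max():
        return 0.0
    h, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = h / h.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])).sum())


def fmi(a: np.ndarray, b: np.ndarray, f: np.ndarray, bins: int = 64) -> float:
    """MI(feature f, feature a) + MI(feature f, feature b), gradient features."""
    a, b, f = _img(a), _img(b), _img(f)
    _same_shape(a, b, f)
    fa, fb, ff = (gradient_magnitude(x) for x in (a, b, f))
    return mutual_information(ff, fa, bins) + mutual_information(ff, fb, bins)


# ---------------------------------------------------------------------------
# visual information fidelity (pixel domain)


def _vif_filter(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    return correlate(x, k, mode="reflect")


def vif(
    ref: np.ndarray,
    dist: np.ndarray,
    sigma_n_sq: float = 2.0,
    scales: int = 4,
) -> float:
    """Pixel-domain VIF over Gaussian scales; 1.0 for identical images.

    Images are taken to the [0, 255] scale internally; ``sigma_n_sq`` is the
    visual-noise variance on that scale.
    """
    ref = _img(ref, 32) * 255.0
    dist = _img(dist, 32) * 255.0
    _same_shape(ref, dist)
    eps = 1e-10
    num = den = 0.0
    for scale in range(1, scales + 1):
        size = 2 ** (scales - scale + 1) + 1
        k = gaussian_kernel(size, size / 5.0)
        if scale > 1:
            ref = _vif_filter(ref, k)[::2, ::2]
            dist = _vif_filter(dist, k)[::2, ::2]
        mu1 = _vif_filter(ref, k)
        mu2 = _vif_filter(dist, k)
        s1 = np.maximum(_vif_filter(ref * ref, k) - mu1 * mu1, 0.0)
        s2 = np.maximum(_vif_filter(dist * dist, k) - mu2 * mu2, 0.0)
        s12 = _vif_filter(ref * dist, k) - mu1 * mu2
        g = s12 / (s1 + eps)
        sv = s2 - g * s12
        g = np.where(s1 < eps, 0.0, g)
        sv = np.where(s1 < eps, s2, sv)
        sv = np.where(s2 < eps, 0.0, sv)
        g = np.where(s2 < eps, 0.0, g)
        sv = np.where(g < 0.0, s2, sv)
        g = np.maximum(g, 0.0)
        sv = np.maximum(sv, eps)
        num += np.sum(np.log10(1.0 + g * g * s1 / (sv + sigma_n_sq)))
        den += np.sum(np.log10(1.0 + s1 / sigma_n_sq))
    if den == 0.0:
        return float("nan")
    return float(num / den)


def vif_fused(a: np.ndarray, b: np.ndarray, f: np.ndarray, **kw) -> float:
    """Average information fidelity of the fused image w.r.t. both sources."""
    return 0.5 * vif(a, f, **kw) + 0.5 * vif(b, f, **kw)


# ---------------------------------------------------------------------------
# report


@dataclass
class MetricReport:
    """The ten fusion metrics for one (a, b, fused) triple."""

    en: float
    ce: float
    rmse: float
    ag: float
    ssim: float
    fmi: float
    qabf: float
    qw: float
    qe: float
    vif: float
    params: dict = field(default_factory=dict)

    NAMES = ("EN", "CE", "RMSE", "AG", "SSIM", "FMI", "Qabf", "Qw", "Qe", "VIF")

    def to_dict(self) -> dict[str, float]:
        vals = (
            self.en,
            self.ce,
            self.rmse,
            self.ag,
            self.ssim,
            self.fmi,
            self.qabf,
            self.qw,
            self.qe,
            self.vif,
        )
        return dict(zip(self.NAMES, vals))


def evaluate_all(
    a: np.ndarray, b: np.ndarray, f: np.ndarray, params: dict | None = None
) -> MetricReport:
    """Compute the full ten-metric report for a fusion triple.

    SSIM is reported as the mean of ssim(a, f) and ssim(b, f); VIF as the
    equal-weight average fidelity to the two sources.
    """
    p = dict(DEFAULT_PARAMS)
    p.update(params or {})
    a, b, f = _img(a), _img(b), _img(f)
    _same_shape(a, b, f)
    ssim_af = ssim(a, f, p["ssim_win"], p["ssim_sigma"], p["ssim_c1"], p["ssim_c2"])
    ssim_bf = ssim(b, f, p["ssim_win"], p["ssim_sigma"], p["ssim_c1"], p["ssim_c2"])
    return MetricReport(
        en=entropy_EN(f, p["hist_bins"]),
        ce=cross_entropy_CE(a, b, f, p["eta_a"], p["eta_b"], p["hist_bins"]),
        rmse=rmse(a, b, f, p["rmse_wa"], p["rmse_wb"]),
        ag=avg_gradient(f),
        ssim=0.5 * (ssim_af + ssim_bf),
        fmi=fmi(a, b, f, p["fmi_bins"]),
        qabf=qabf(a, b, f, p["q0_win"]),
        qw=qw(a, b, f, p["q0_win"]),
        qe=qe(a, b, f, p["qe_alpha"], p["q0_win"]),
        vif=vif_fused(a, b, f, sigma_n_sq=p["vif_sigma_n_sq"], scales=p["vif_scales"]),
        params=p,
    )
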