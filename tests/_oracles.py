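"""Naive nested-loop reference implementations of the fusion metrics.

These are deliberately slow, scalar, and independent of the vectorized code
paths in ``medfuse.metrics``: plain Python loops over pixels, windows and
histogram bins.  They exist only to pin the package implementations on
small images.
"""

from __future__ import annotations

import math

import numpy as np

VAR_TOL = 1e-12


def hist256(x: np.ndarray, bins: int = 256) -> np.ndarray:
    h = [0] * bins
    for v in x.ravel():
        b = min(int(v * bins), bins - 1)
        h[b] += 1
    return np.array(h) / x.size


def en(f: np.ndarray) -> float:
    p = hist256(f)
    return -sum(pi * math.log2(pi) for pi in p if pi > 0)


def sym_div(p: np.ndarray, q: np.ndarray, smooth: float = 1e-12) -> float:
    total = 0.0
    for pi, qi in zip(p, q):
        pi, qi = pi + smooth, qi + smooth
        total += pi * math.log(pi / qi)
    for pi, qi in zip(p, q):
        pi, qi = pi + smooth, qi + smooth
        total += qi * math.log(qi / pi)
    return total


def ce(a: np.ndarray, b: np.ndarray, f: np.ndarray, eta_a=0.7, eta_b=0.3) -> float:
    pa, pb, pf = hist256(a), hist256(b), hist256(f)
    return eta_a * sym_div(pa, pf) + eta_b * sym_div(pb, pf)


def rmse(a: np.ndarray, b: np.ndarray, f: np.ndarray, wa=0.5, wb=0.5) -> float:
    m, n = f.shape

    def one(src):
        s = 0.0
        for i in range(m):
            for j in range(n):
                s += (src[i, j] - f[i, j]) ** 2
        return math.sqrt(s / (m * n))

    return wa * one(a) + wb * one(b)


def ag(f: np.ndarray) -> float:
    m, n = f.shape
    total = 0.0
    for i in range(m - 1):
        for j in range(n - 1):
            dx = f[i, j] - f[i + 1, j]
            dy = f[i, j] - f[i, j + 1]
            total += math.sqrt((dx * dx + dy * dy) / 2.0)
    return total / ((m - 1) * (n - 1))


def _gauss_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    k = np.empty((size, size))
    c = (size - 1) / 2.0
    for u in range(size):
        for v in range(size):
            k[u, v] = math.exp(-(((u - c) ** 2) + ((v - c) ** 2)) / (2 * sigma**2))
    return k / k.sum()


def ssim(x, y, win=11, sigma=1.5, c1=0.01**2, c2=0.03**2) -> float:
    k = _gauss_window(win, sigma)
    m, n = x.shape
    vals = []
    for i in range(m - win + 1):
        for j in range(n - win + 1):
            wx = x[i : i + win, j : j + win]
            wy = y[i : i + win, j : j + win]
            mux = float((k * wx).sum())
            muy = float((k * wy).sum())
            vx = float((k * wx * wx).sum()) - mux * mux
            vy = float((k * wy * wy).sum()) - muy * muy
            cxy = float((k * wx * wy).sum()) - mux * muy
            vals.append(
                ((2 * mux * muy + c1) * (2 * cxy + c2))
                / ((mux**2 + muy**2 + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))


def _win_stats(w: np.ndarray) -> tuple[float, float]:
    mu = float(w.mean())
    var = float((w * w).mean()) - mu * mu
    return mu, var


def _q0_windows(a, b, win=8):
    m, n = a.shape
    out = []
    for i in range(m - win + 1):
        for j in range(n - win + 1):
            wa = a[i : i + win, j : j + win]
            wb = b[i : i + win, j : j + win]
            mua, va = _win_stats(wa)
            mub, vb = _win_stats(wb)
            cab = float((wa * wb).mean()) - mua * mub
            valid = va > VAR_TOL and vb > VAR_TOL
            if valid:
                q = (
                    (cab / math.sqrt(va * vb))
                    * (2 * mua * mub / (mua**2 + mub**2))
                    * (2 * math.sqrt(va) * math.sqrt(vb) / (va + vb))
                )
            else:
                q = 0.0
            out.append((q, valid, va, vb))
    return out


def q0(a, b, win=8) -> float:
    vals = [q for q, valid, _, _ in _q0_windows(a, b, win) if valid]
    return float(np.mean(vals))


def _qabf_windows(a, b, f, win=8):
    qaf = _q0_windows(a, f, win)
    qbf = _q0_windows(b, f, win)
    sa = [va for _, _, va, _ in _q0_windows(a, a, win)]
    sb = [va for _, _, va, _ in _q0_windows(b, b, win)]
    rows = []
    for (q1, v1, _, _), (q2, v2, _, _), s1, s2 in zip(qaf, qbf, sa, sb):
        lam = s1 / (s1 + s2) if (s1 + s2) > 0 else 0.5
        rows.append((lam * q1 + (1 - lam) * q2, max(s1, s2), v1 and v2))
    return rows


def qabf(a, b, f, win=8) -> float:
    rows = _qabf_windows(a, b, f, win)
    vals = [c for c, _, valid in rows if valid]
    return float(np.mean(vals))


def qw(a, b, f, win=8) -> float:
    rows = _qabf_windows(a, b, f, win)
    cs = [s for _, s, valid in rows if valid]
    vals = [c for c, _, valid in rows if valid]
    total = sum(cs)
    if total <= 0:
        return float(np.mean(vals))
    return float(sum(s / total * c for s, c in zip(cs, vals)))


def grad_mag(img: np.ndarray) -> np.ndarray:
    m, n = img.shape
    gx = np.empty((m, n))
    gy = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            if 0 < i < m - 1:
                gy[i, j] = (img[i + 1, j] - img[i - 1, j]) / 2.0
            elif i == 0:
                gy[i, j] = img[1, j] - img[0, j]
            else:
                gy[i, j] = img[m - 1, j] - img[m - 2, j]
            if 0 < j < n - 1:
                gx[i, j] = (img[i, j + 1] - img[i, j - 1]) / 2.0
            elif j == 0:
                gx[i, j] = img[i, 1] - img[i, 0]
            else:
                gx[i, j] = img[i, n - 1] - img[i, n - 2]
    return np.sqrt(gx**2 + gy**2)


def qe(a, b, f, alpha=0.5, win=8) -> float:
    q1 = qw(a, b, f, win)
    q2 = qw(grad_mag(a), grad_mag(b), grad_mag(f), win)
    return max(q1, 0.0) ** (1 - alpha) * max(q2, 0.0) ** alpha


def mi(x: np.ndarray, y: np.ndarray, bins: int = 64) -> float:
    xr, yr = x.ravel(), y.ravel()
    xmin, xmax = xr.min(), xr.max()
    ymin, ymax = yr.min(), yr.max()
    if xmin == xmax or ymin == ymax:
        return 0.0
    h = np.zeros((bins, bins))
    for xv, yv in zip(xr, yr):
        bi = min(int((xv - xmin) / (xmax - xmin) * bins), bins - 1)
        bj = min(int((yv - ymin) / (ymax - ymin) * bins), bins - 1)
        h[bi, bj] += 1
    pxy = h / h.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    total = 0.0
    for i in range(bins):
        for j in range(bins):
            if pxy[i, j] > 0:
                total += pxy[i, j] * math.log2(pxy[i, j] / (px[i] * py[j]))
    return total


def fmi(a, b, f, bins=64) -> float:
    fa, fb, ff = grad_mag(a), grad_mag(b), grad_mag(f)
    return mi(ff, fa, bins) + mi(ff, fb, bins)
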