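"""Autoencoder training with the mixed cross-entropy + SSIM loss.

The encoder and decoder are trained jointly to reconstruct single grayscale
images (the fusion stage is bypassed), minimizing

    L = alpha * CE(I, O) + beta * (1 - SSIM(I, O)),

with per-pixel mean binary cross-entropy and the Gaussian-window SSIM of
:mod:`medfuse.metrics`.  Defaults: alpha=500, beta=1, learning rate 5e-4,
batch size 32, 10 epochs, exponential per-epoch decay lr = 0.95^epoch * lr0.

Gradients are computed analytically (no autodiff framework): the SSIM
gradient follows from the chain rule through the Gaussian-filter local
statistics, whose adjoint for symmetric kernels and valid-mode filtering is
full-mode convolution with the same kernel.  Adam with default moment
parameters is the optimizer; everything is seeded, so a run is bit
reproducible on one machine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .metrics import gaussian_kernel, ssim_stats
from .network import (
    NetParams,
    autoencoder_backward,
    decoder_forward,
    encoder_forward,
    init_params,
)

__all__ = [
    "TrainConfig",
    "TrainResult",
    "cross_entropy_loss",
    "ssim_loss",
    "mixed_loss",
    "lr_schedule",
    "train_autoencoder",
]

logger = logging.getLogger(__name__)

EPS_CLAMP = 1e-7


@dataclass
class TrainConfig:
    lr0: float = 0.0005
    batch_size: int = 32
    epochs: int = 10
    alpha: float = 500.0
    beta: float = 1.0
    seed: int = 0
    widths: dict | None = None
    ssim_win: int = 11
    ssim_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.lr0 <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr0 > 0, batch_size >= 1, epochs >= 1 required")
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta == 0:
            raise ValueError("need alpha, beta >= 0 with alpha + beta > 0")


@dataclass
class TrainResult:
    params: NetParams
    epoch_losses: list[float] = field(default_factory=list)
    config: TrainConfig | None = None


def cross_entropy_loss(i: np.ndarray, o: np.ndarray) -> float:
    """Per-pixel mean Bernoulli cross entropy -[I log O + (1-I) log(1-O)]."""
    i = np.asarray(i, dtype=float)
    o = np.asarray(o, dtype=float)
    if i.shape != o.shape:
        raise ValueError(f"shape mismatch {i.shape} vs {o.shape}")
    oc = np.clip(o, EPS_CLAMP, 1.0 - EPS_CLAMP)
    return float(np.mean(-(i * np.log(oc) + (1.0 - i) * np.log1p(-oc))))


def _ce_grad(i: np.ndarray, o: np.ndarray) -> np.ndarray:
    oc = np.clip(o, EPS_CLAMP, 1.0 - EPS_CLAMP)
    return (oc - i) / (oc * (1.0 - oc)) / i.size


def _ssim_and_grad(
    x: np.ndarray,
    y: np.ndarray,
    kernel: np.ndarray,
    c1: float = 0.01**2,
    c2: float = 0.03**2,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-image mean SSIM and its gradient w.r.t. ``y`` for a batch [B,H,W].

    Local statistics use valid-mode Gaussian filtering; their adjoint is a
    full-mode convolution with the (symmetric) kernel.
    """
    mux, muy, vx, vy, cxy = ssim_stats(x, y, kernel)
    a1 = 2.0 * mux * muy + c1
    b1 = mux**2 + muy**2 + c1
    a2 = 2.0 * cxy + c2
    b2 = vx + vy + c2
    s = (a1 * a2) / (b1 * b2)
    n_win = s.shape[-1] * s.shape[-2]
    mean_s = s.mean(axis=(-1, -2))

    # partials of S w.r.t. mu_y, var_y and cov_xy
    d_cov = 2.0 * a1 / (b1 * b2)
    d_var = -(a1 * a2) / (b1 * b2 * b2)
    d_mu = 2.0 * mux * a2 / (b1 * b2) - 2.0 * muy * (a1 * a2) / (b1 * b1 * b2)
    # fold the dependence of var_y = K*y^2 - mu_y^2 and cov = K*xy - mu_x mu_y
    g_mu = d_mu - 2.0 * muy * d_var - mux * d_cov
    k = kernel if x.ndim == 2 else kernel[None]
    grad = (
        fftconvolve(g_mu, k, mode="full")
        + 2.0 * y * fftconvolve(d_var, k, mode="full")
        + x * fftconvolve(d_cov, k, mode="full")
    ) / n_win
    return mean_s, grad


def ssim_loss(
    i: np.ndarray, o: np.ndarray, win_size: int = 11, sigma: float = 1.5
) -> float:
    """1 - SSIM(I, O); in [0, 2] since SSIM is bounded by [-1, 1]."""
    i = np.asarray(i, dtype=float)
    o = np.asarray(o, dtype=float)
    if i.shape != o.shape:
        raise ValueError(f"shape mismatch {i.shape} vs {o.shape}")
    if min(i.shape) < win_size:
        raise ValueError(f"image {i.shape} smaller than SSIM window {win_size}")
    s, _ = _ssim_and_grad(i, o, gaussian_kernel(win_size, sigma))
    return float(1.0 - s)


def mixed_loss(
    i: np.ndarray, o: np.ndarray, alpha: float = 500.0, beta: float = 1.0
) -> float:
    """alpha * cross-entropy + beta * (1 - SSIM)."""
    return alpha * cross_entropy_loss(i, o) + beta * ssim_loss(i, o)


def lr_schedule(epoch_num: int, lr0: float) -> float:
    """Exponentially decayed learning rate 0.95^epoch * lr0."""
    if epoch_num < 0:
        raise ValueError(f"epoch_num must be >= 0, got {epoch_num}")
    return 0.95**epoch_num * lr0


class _Adam:
    def __init__(self, shapes, dtype, b1=0.9, b2=0.999, eps=1e-8):
        self.b1, self.b2, self.eps = b1, b2, eps
        self.m = {k: np.zeros(s, dtype=dtype) for k, s in shapes.items()}
        self.v = {k: np.zeros(s, dtype=dtype) for k, s in shapes.items()}
        self.t = 0

    def step(self, values: dict, grads: dict, lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for key, g in grads.items():
            m = self.m[key]
            v = self.v[key]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            values[key] -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _batch_loss_and_grads(params, x, cfg, kernel):
    """Forward + backward on one batch ``x [B,1,H,W]``; returns (loss, grads)."""
    cache: dict = {}
    stack = encoder_forward(params, x, cache=cache)
    o = decoder_forward(params, stack, cache=cache)
    i2, o2 = x[:, 0], o[:, 0]

    ce = cross_entropy_loss(i2, o2)
    s, ds_dy = _ssim_and_grad(i2, o2, kernel)
    loss = cfg.alpha * ce + cfg.beta * float(1.0 - s.mean())
    batch = x.shape[0]
    d_o = cfg.alpha * _ce_grad(i2, o2) - cfg.beta * ds_dy / batch
    grads = autoencoder_backward(params, cache, d_o[:, None])
    return loss, grads


def train_autoencoder(
    corpus: list[np.ndarray], cfg: TrainConfig | None = None
) -> TrainResult:
    """Train encoder+decoder to reconstruct the corpus images.

    All corpus images must share one shape (callers resize beforehand).
    Training runs in float32 for speed; the returned parameters are cast to
    float64.  Raises if the loss goes non-finite.
    """
    cfg = cfg or TrainConfig()
    if not corpus:
        raise ValueError("training corpus is empty")
    data = np.stack([np.asarray(im, dtype=np.float32) for im in corpus])
    if data.ndim != 3:
        raise ValueError("corpus images must be 2-D and share one shape")
    if min(data.shape[1:]) < cfg.ssim_win:
        raise ValueError("training images smaller than the SSIM window")
    data = data[:, None]  # [N,1,H,W]

    params64 = init_params(seed=cfg.seed, widths=cfg.widths)
    params = params64.astype(np.float32)
    kernel = gaussian_kernel(cfg.ssim_win, cfg.ssim_sigma).astype(np.float32)

    flat_shapes = {
        f"{name}.{part}": arr.shape
        for name, (k, b) in params.layers.items()
        for part, arr in (("kernel", k), ("bias", b))
    }
    opt = _Adam(flat_shapes, np.float32)
    rng = np.random.default_rng(cfg.seed + 1)
    n = data.shape[0]
    epoch_losses: list[float] = []
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg.lr0)
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            x = data[order[start : start + cfg.batch_size]]
            loss, grads = _batch_loss_and_grads(params, x, cfg, kernel)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, "
                    f"batch starting {start}"
                )
            values = {}
            flat_grads = {}
            for name, (k, b) in params.layers.items():
                values[f"{name}.kernel"] = k
                values[f"{name}.bias"] = b
                gk, gb = grads[name]
                flat_grads[f"{name}.kernel"] = gk
                flat_grads[f"{name}.bias"] = gb
            opt.step(values, flat_grads, lr)
            batch_losses.append(loss)
        epoch_losses.append(float(np.mean(batch_losses)))
        logger.info(
            "epoch %d/%d lr=%.2e loss=%.5f",
            epoch + 1,
            cfg.epochs,
            lr,
            epoch_losses[-1],
        )
    return TrainResult(params=params.astype(np.float64), epoch_losses=epoch_losses, config=cfg)
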