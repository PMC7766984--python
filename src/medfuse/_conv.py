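"""3x3 same-padded convolution primitives (im2col + BLAS) with backprop.

No deep-learning framework is assumed; the network here is seven 3x3
convolution layers, so an explicit im2col lowering onto matrix multiplies
is both fast enough on one CPU and exactly differentiable by hand.

Layout conventions: activations are ``[B, C, H, W]``; kernels are
``[C_out, C_in, 3, 3]``; biases ``[C_out]``.  Padding is one pixel of
zeros on each side (stride 1), so spatial shape is always preserved.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["im2col", "conv3x3", "conv3x3_backward", "selu", "selu_grad"]

#: canonical self-normalizing SeLU constants
SELU_LAMBDA = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772


def im2col(x: np.ndarray) -> np.ndarray:
    """Lower ``x [B,C,H,W]`` to patch-matrix ``[B*H*W, C*9]`` (zero pad 1)."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # [B,C,H,W,3,3] view
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * 9)
    return np.ascontiguousarray(cols)


def conv3x3(
    x: np.ndarray, k: np.ndarray, bias: np.ndarray, cols: np.ndarray | None = None
) -> np.ndarray:
    """Same-padded stride-1 convolution (cross-correlation, CNN convention)."""
    b, c, h, w = x.shape
    co = k.shape[0]
    if k.shape != (co, c, 3, 3):
        raise ValueError(f"kernel shape {k.shape} incompatible with input C={c}")
    if cols is None:
        cols = im2col(x)
    y = cols @ k.reshape(co, c * 9).T
    y += bias
    return y.reshape(b, h, w, co).transpose(0, 3, 1, 2)


def conv3x3_backward(
    dy: np.ndarray, cols: np.ndarray, k: np.ndarray, x_shape: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of conv3x3: returns ``(dx, dk, dbias)``.

    ``cols`` must be the im2col matrix cached from the forward pass.
    """
    b, c, h, w = x_shape
    co = k.shape[0]
    dyf = dy.transpose(0, 2, 3, 1).reshape(b * h * w, co)
    dk = (dyf.T @ cols).reshape(co, c, 3, 3)
    dbias = dyf.sum(axis=0)
    dcols = (dyf @ k.reshape(co, c * 9)).reshape(b, h, w, c, 3, 3)
    # col2im: scatter-add the 9 taps back onto the padded input grid
    dxp = np.zeros((b, c, h + 2, w + 2), dtype=dy.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return dxp[:, :, 1:-1, 1:-1], dk, dbias


def selu(
    x: np.ndarray, lam: float = SELU_LAMBDA, alpha: float = SELU_ALPHA
) -> np.ndarray:
    """Scaled exponential linear unit: lam*x (x>0), lam*alpha*(e^x - 1) (x<=0)."""
    return np.where(x > 0, lam * x, (lam * alpha) * np.expm1(np.minimum(x, 0.0)))


def selu_grad(
    x: np.ndarray, lam: float = SELU_LAMBDA, alpha: float = SELU_ALPHA
) -> np.ndarray:
    """d selu / dx evaluated at pre-activation ``x``."""
    return np.where(x > 0, lam, (lam * alpha) * np.exp(np.minimum(x, 0.0)))
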