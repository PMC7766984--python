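"""Dense-reuse convolutional encoder/decoder.

Encoder: one stem convolution C1 followed by a three-layer detail block
(CIDN1-3) in which the second layer is the single feature-reuse layer — it
takes the concatenation of all previous outputs (C1 and CIDN1) as input and
its output feeds both the next layer and the fusion stage.  The feature
stack handed to fusion is the concatenation of the CIDN2 and CIDN3 outputs.
Decoder: three convolutions D1-D3; D1/D2 are SeLU-activated, D3 ends in a
logistic squashing so outputs are valid Bernoulli means for the
cross-entropy reconstruction loss.

All convolutions are 3x3, stride 1, zero same-padding, so any input of at
least 8x8 passes through with its shape preserved.

Parameters live in :class:`NetParams`, a plain mapping of layer name to
(kernel, bias) with an architecture descriptor, serialized to a single
``.npz`` checkpoint with the descriptor embedded as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._conv import (
    SELU_ALPHA,
    SELU_LAMBDA,
    conv3x3,
    conv3x3_backward,
    im2col,
    selu,
    selu_grad,
)

__all__ = ["NetParams", "FeatureStack", "init_params", "encode", "decode"]

FORMAT_VERSION = 1

#: encoder/decoder layer order
LAYERS = ("c1", "cidn1", "cidn2", "cidn3", "d1", "d2", "d3")

DEFAULT_WIDTHS = {"c1": 16, "cidn": 16, "d1": 16, "d2": 8}


class ArchitectureError(ValueError):
    """Parameter shapes inconsistent with the concatenation wiring."""


@dataclass
class FeatureStack:
    """Ordered same-size feature maps ``maps [n, H, W]`` for one source."""

    maps: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 3 or self.maps.shape[0] < 1:
            raise ValueError(f"expected [n,H,W] maps, got {self.maps.shape}")

    @property
    def n(self) -> int:
        return self.maps.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]


@dataclass
class NetParams:
    """All kernels/biases plus an architecture descriptor."""

    layers: dict[str, tuple[np.ndarray, np.ndarray]]
    arch: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.arch.setdefault("kernel", 3)
        self.arch.setdefault("selu_lambda", SELU_LAMBDA)
        self.arch.setdefault("selu_alpha", SELU_ALPHA)
        self.arch.setdefault("format_version", FORMAT_VERSION)
        self._validate()

    def _validate(self) -> None:
        missing = [name for name in LAYERS if name not in self.layers]
        if missing:
            raise ArchitectureError(f"missing layers: {missing}")
        for name, (k, b) in self.layers.items():
            if k.ndim != 4 or k.shape[2:] != (3, 3):
                raise ArchitectureError(f"layer {name}: kernels must be [O,I,3,3]")
            if b.shape != (k.shape[0],):
                raise ArchitectureError(f"layer {name}: bias/kernel width mismatch")
        w = {name: self.layers[name][0].shape for name in LAYERS}
        wc1, wc = w["c1"][0], w["cidn1"][0]
        wiring = [
            (w["c1"][1], 1, "c1 input"),
            (w["cidn1"][1], wc1, "cidn1 input"),
            (w["cidn2"][1], wc1 + wc, "cidn2 input (concat of c1 and cidn1)"),
            (w["cidn3"][1], w["cidn2"][0], "cidn3 input"),
            (w["d1"][1], w["cidn2"][0] + w["cidn3"][0], "d1 input (fused stack)"),
            (w["d2"][1], w["d1"][0], "d2 input"),
            (w["d3"][1], w["d2"][0], "d3 input"),
            (w["d3"][0], 1, "d3 output"),
        ]
        for got, want, what in wiring:
            if got != want:
                raise ArchitectureError(f"{what}: expected width {want}, got {got}")

    @property
    def encoder_out_channels(self) -> int:
        return self.layers["cidn2"][0].shape[0] + self.layers["cidn3"][0].shape[0]

    def astype(self, dtype) -> "NetParams":
        return NetParams(
            {n: (k.astype(dtype), b.astype(dtype)) for n, (k, b) in self.layers.items()},
            arch=dict(self.arch),
        )

    def save(self, path) -> None:
        payload = {}
        for name, (k, b) in self.layers.items():
            payload[f"{name}.kernel"] = k
            payload[f"{name}.bias"] = b
        payload["arch_json"] = np.frombuffer(
            json.dumps(self.arch).encode(), dtype=np.uint8
        )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "NetParams":
        with np.load(path) as data:
            arch = json.loads(bytes(data["arch_json"]).decode())
            layers = {
                name: (data[f"{name}.kernel"], data[f"{name}.bias"])
                for name in LAYERS
            }
        return cls(layers, arch=arch)


def init_params(
    seed: int = 0,
    widths: dict | None = None,
    dtype=np.float64,
    selu_lambda: float = SELU_LAMBDA,
    selu_alpha: float = SELU_ALPHA,
) -> NetParams:
    """Seeded variance-scaling (LeCun normal) initialization.

    LeCun-normal kernels (std = 1/sqrt(fan_in)) keep activations in the
    self-normalizing regime of SeLU; biases start at zero.
    """
    wd = dict(DEFAULT_WIDTHS)
    wd.update(widths or {})
    wc1, wc, wd1, wd2 = wd["c1"], wd["cidn"], wd["d1"], wd["d2"]
    shapes = {
        "c1": (wc1, 1),
        "cidn1": (wc, wc1),
        "cidn2": (wc, wc1 + wc),
        "cidn3": (wc, wc),
        "d1": (wd1, wc + wc),
        "d2": (wd2, wd1),
        "d3": (1, wd2),
    }
    rng = np.random.default_rng(seed)
    layers = {}
    for name, (co, ci) in shapes.items():
        std = 1.0 / np.sqrt(ci * 9)
        layers[name] = (
            rng.normal(0.0, std, size=(co, ci, 3, 3)).astype(dtype),
            np.zeros(co, dtype=dtype),
        )
    return NetParams(
        layers,
        arch={
            "widths": {k: int(v) for k, v in wd.items()},
            "selu_lambda": selu_lambda,
            "selu_alpha": selu_alpha,
            "seed": int(seed),
        },
    )


def _check_input(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if min(img.shape) < 8:
        raise ValueError(f"image must be at least 8x8, got {img.shape}")
    return img


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def encoder_forward(
    params: NetParams, x: np.ndarray, cache: dict | None = None
) -> np.ndarray:
    """Run the encoder on ``x [B,1,H,W]``; returns the [B,2w,H,W] stack.

    When ``cache`` is a dict, im2col matrices and pre-activations needed by
    :func:`encoder_backward` are stored in it.
    """
    sl = params.arch["selu_lambda"]
    sa = params.arch["selu_alpha"]

    def layer(name: str, inp: np.ndarray) -> np.ndarray:
        k, b = params.layers[name]
        cols = im2col(inp)
        pre = conv3x3(inp, k, b, cols=cols)
        if cache is not None:
            cache[name] = (cols, pre, inp.shape)
        return selu(pre, sl, sa)

    h0 = layer("c1", x)
    h1 = layer("cidn1", h0)
    h2 = layer("cidn2", np.concatenate([h0, h1], axis=1))
    h3 = layer("cidn3", h2)
    return np.concatenate([h2, h3], axis=1)


def decoder_forward(
    params: NetParams, stack: np.ndarray, cache: dict | None = None
) -> np.ndarray:
    """Run the decoder on a fused stack ``[B,2w,H,W]``; returns ``[B,1,H,W]``."""
    sl = params.arch["selu_lambda"]
    sa = params.arch["selu_alpha"]
    z = stack
    for name in ("d1", "d2", "d3"):
        k, b = params.layers[name]
        cols = im2col(z)
        pre = conv3x3(z, k, b, cols=cols)
        if cache is not None:
            cache[name] = (cols, pre, z.shape)
        z = _sigmoid(pre) if name == "d3" else selu(pre, sl, sa)
    if cache is not None:
        cache["output"] = z
    return z


def autoencoder_backward(
    params: NetParams, cache: dict, d_out: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Backprop d(loss)/d(output) through decoder and encoder.

    Returns per-layer ``(d_kernel, d_bias)``; the input gradient is dropped.
    """
    sl = params.arch["selu_lambda"]
    sa = params.arch["selu_alpha"]
    grads: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def back(name: str, dz: np.ndarray, through_selu: bool) -> np.ndarray:
        cols, pre, in_shape = cache[name]
        if through_selu:
            dpre = dz * selu_grad(pre, sl, sa)
        else:
            dpre = dz
        dx, dk, db = conv3x3_backward(dpre, cols, params.layers[name][0], in_shape)
        grads[name] = (dk, db)
        return dx

    o = cache["output"]
    dpre3 = d_out * o * (1.0 - o)  # logistic output layer
    dz = back("d3", dpre3, through_selu=False)
    dz = back("d2", dz, through_selu=True)
    d_stack = back("d1", dz, through_selu=True)

    w2 = params.layers["cidn2"][0].shape[0]
    d_h2, d_h3 = d_stack[:, :w2], d_stack[:, w2:]
    d_h2 = d_h2 + back("cidn3", d_h3, through_selu=True)
    d_cat = back("cidn2", d_h2, through_selu=True)
    wc1 = params.layers["c1"][0].shape[0]
    d_h0, d_h1 = d_cat[:, :wc1], d_cat[:, wc1:]
    d_h0 = d_h0 + back("cidn1", d_h1, through_selu=True)
    back("c1", d_h0, through_selu=True)
    return grads


def encode(img: np.ndarray, params: NetParams, source: str = "") -> FeatureStack:
    """Encode a single grayscale image (>= 8x8) into its feature stack."""
    img = _check_input(img)
    stack = encoder_forward(params, img[None, None, :, :])
    return FeatureStack(stack[0], source=source)


def decode(fused: FeatureStack, params: NetParams) -> np.ndarray:
    """Decode a fused feature stack back to a single (0,1) grayscale image."""
    if fused.n != params.encoder_out_channels:
        raise ArchitectureError(
            f"fused stack has {fused.n} maps, decoder expects "
            f"{params.encoder_out_channels}"
        )
    out = decoder_forward(params, fused.maps[None])
    return out[0, 0]
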