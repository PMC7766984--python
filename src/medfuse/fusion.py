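"""Trace-weighted feature fusion.

Each source's feature stack is reduced to a single scalar saliency: the sum
over its maps of the (absolute) matrix trace.  For a square symmetric map
the trace is the sum of its eigenvalues, so a stack whose maps carry more
spectral energy receives more weight.  Weights are normalized to a
probability vector and the fused stack is the per-map convex combination of
the source stacks.

SeLU feature maps can have negative traces; by default traces are
aggregated in absolute value so weights stay non-negative and well defined.
``signed_traces=True`` keeps the literal signed sum (weights may then fall
outside [0, 1]).
"""

from __future__ import annotations

import numpy as np

from .network import FeatureStack

__all__ = ["map_trace", "fusion_weights", "fuse", "fuse_stacks"]


def map_trace(m: np.ndarray) -> float:
    """Sum of main-diagonal entries; for rectangular maps, the min(M,N) ones."""
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D map, got shape {m.shape}")
    return float(np.trace(m))


def _check_stacks(stacks: list[FeatureStack]) -> None:
    if len(stacks) < 2:
        raise ValueError("need at least two source stacks")
    n, shape = stacks[0].n, stacks[0].spatial_shape
    for s in stacks[1:]:
        if s.n != n or s.spatial_shape != shape:
            raise ValueError(
                f"mismatched stacks: {(s.n, s.spatial_shape)} vs {(n, shape)}"
            )


def fusion_weights(
    stacks: list[FeatureStack], signed_traces: bool = False
) -> np.ndarray:
    """One weight per source from per-stack trace sums, normalized to 1.

    All-zero saliencies degenerate to uniform weights 1/k.
    """
    _check_stacks(stacks)
    traces = np.array(
        [[map_trace(m) for m in s.maps] for s in stacks]
    )  # [k, n]
    if signed_traces:
        sal = traces.sum(axis=1)
    else:
        sal = np.abs(traces).sum(axis=1)
    total = sal.sum()
    if total == 0:
        return np.full(len(stacks), 1.0 / len(stacks))
    return sal / total


def fuse(stacks: list[FeatureStack], w: np.ndarray) -> FeatureStack:
    """Per-map weighted combination: f^j = sum_i w_i * phi_i^j."""
    _check_stacks(stacks)
    w = np.asarray(w, dtype=float)
    if w.shape != (len(stacks),):
        raise ValueError(f"expected {len(stacks)} weights, got shape {w.shape}")
    fused = np.tensordot(w, np.stack([s.maps for s in stacks]), axes=(0, 0))
    return FeatureStack(fused, source="fused")


def fuse_stacks(
    stacks: list[FeatureStack],
    strategy: str = "trace",
    signed_traces: bool = False,
) -> tuple[FeatureStack, np.ndarray]:
    """Fuse with the configured strategy; returns (fused stack, weights).

    ``"trace"`` is the trace-weighted rule; ``"mean"`` is the plain addition
    (uniform-average) baseline.
    """
    if strategy == "trace":
        w = fusion_weights(stacks, signed_traces=signed_traces)
    elif strategy == "mean":
        _check_stacks(stacks)
        w = np.full(len(stacks), 1.0 / len(stacks))
    else:
        raise ValueError(f"unknown fusion strategy {strategy!r}")
    return fuse(stacks, w), w
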