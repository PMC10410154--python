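"""Closed-form operation and weight counts for spatiotemporal layers.

For an output ST tensor of shape [T, H, W, C] produced from K input
channels by an (I, J) kernel (plus a temporal kernel extent U for 3-D
convolution), write R = T*H*W*C (output elements over the sequence) and
Q = I*J*K (multiply-accumulates per output element of a 2-D convolution).
The per-layer costs are then:

=============  ==================  ==================  ====================
layer          MUL                 ADD                 weights
=============  ==================  ==================  ====================
ConvLIAF       (Q+1)*R             (Q+2)*R             (Q+1)*C
ConvLIF        R                   (Q+2)*R             (Q+1)*C
Conv2D (TD)    Q*R                 Q*R                 (Q+1)*C
Conv3D         U*Q*R               U*Q*R               (U*Q+1)*C
ConvLSTM       (4*(Q+I*J*C)+3)*R   (4*(Q+I*J*C)+1)*R   (Q+I*J*C+1)*4*C
=============  ==================  ==================  ====================

The LIF/LIAF rows include the elementwise neuron dynamics (integrate,
fire, reset, leak); ConvLIF needs only R multiplications because its
binary spike inputs turn the synaptic multiply-accumulate into pure
accumulation.  Normalization layers are excluded.  Weight counts are
synaptic weights plus biases only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError

__all__ = ["LayerShape", "KINDS", "count_ops", "count_weights",
           "brute_force_weights", "ratio_report"]

KINDS = ("conv_liaf", "conv_lif", "conv2d_td", "conv3d", "conv_lstm")


@dataclass(frozen=True)
class LayerShape:
    """Geometry of one layer: output extents, input channels, kernel."""

    t: int
    h: int
    w: int
    c: int  # output channels
    k: int  # input channels
    i: int = 3
    j: int = 3
    u: int = 1  # temporal kernel extent (Conv3D only)

    def __post_init__(self):
        if min(self.t, self.h, self.w, self.c, self.k, self.i, self.j, self.u) < 1:
            raise ContractError("all layer extents must be positive integers")

    @property
    def r_cnt(self) -> int:
        return self.t * self.h * self.w * self.c

    @property
    def q_cnt(self) -> int:
        return self.i * self.j * self.k


def count_ops(kind: str, shape: LayerShape) -> tuple[int, int]:
    """Exact (multiplications, additions) for one layer over T timesteps."""
    r, q = shape.r_cnt, shape.q_cnt
    if kind == "conv_liaf":
        return (q + 1) * r, (q + 2) * r
    if kind == "conv_lif":
        return r, (q + 2) * r
    if kind == "conv2d_td":
        return q * r, q * r
    if kind == "conv3d":
        return shape.u * q * r, shape.u * q * r
    if kind == "conv_lstm":
        gate = 4 * (q + shape.i * shape.j * shape.c)
        return (gate + 3) * r, (gate + 1) * r
    raise ContractError(f"unknown layer kind {kind!r}; known: {KINDS}")


def count_weights(kind: str, shape: LayerShape) -> int:
    """Exact weight (synapse + bias) count for one layer."""
    q, c = shape.q_cnt, shape.c
    if kind in ("conv_liaf", "conv_lif", "conv2d_td"):
        return (q + 1) * c
    if kind == "conv3d":
        return (shape.u * q + 1) * c
    if kind == "conv_lstm":
        return (q + shape.i * shape.j * shape.c + 1) * 4 * c
    raise ContractError(f"unknown layer kind {kind!r}; known: {KINDS}")


def _instantiate_param_arrays(kind: str, shape: LayerShape) -> list[np.ndarray]:
    """Materialise the actual parameter arrays of a layer of this kind."""
    c, k, i, j, u = shape.c, shape.k, shape.i, shape.j, shape.u
    if kind in ("conv_liaf", "conv_lif", "conv2d_td"):
        # instantiate the real ST block and take its synaptic parameters
        from .blocks import BlockConfig, build_block

        cfg = BlockConfig(kind=kind, in_channels=k, out_channels=c, kernel=(i, j))
        blk = build_block(cfg, np.random.default_rng(0))
        return [p.data for p in blk.synapse_parameters()]
    if kind == "conv3d":
        return [np.zeros((c, k, u, i, j)), np.zeros(c)]
    if kind == "conv_lstm":
        arrays = []
        for _gate in range(4):  # input, forget, cell, output gates
            arrays.append(np.zeros((c, k, i, j)))  # input kernel
            arrays.append(np.zeros((c, c, i, j)))  # recurrent kernel
            arrays.append(np.zeros(c))  # bias
        return arrays
    raise ContractError(f"unknown layer kind {kind!r}; known: {KINDS}")


def brute_force_weights(kind: str, shape: LayerShape) -> int:
    """Parameter count by enumerating instantiated parameter arrays."""
    return int(sum(a.size for a in _instantiate_param_arrays(kind, shape)))


def ratio_report(shape: LayerShape, reference: str = "conv_liaf") -> dict:
    """Total-operation (MUL+ADD) and weight ratios of each kind vs a reference.

    Returns per-kind totals plus ratios and their nearest-integer summary.
    """
    ref_mul, ref_add = count_ops(reference, shape)
    ref_total = ref_mul + ref_add
    report = {}
    for kind in KINDS:
        mul, add = count_ops(kind, shape)
        total = mul + add
        report[kind] = {
            "mul": mul,
            "add": add,
            "total_ops": total,
            "weights": count_weights(kind, shape),
            "ops_ratio": total / ref_total,
            "ops_ratio_rounded": int(round(total / ref_total)),
        }
    return report
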