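"""Spatiotemporal building blocks.

An ST block chains synaptic integration (2-D convolution or a linear map),
optional homeostasis (batch normalization), and neural dynamics (a LIF/LIAF
layer, optionally a configured LIF+ variant).  A block therefore consumes
one frame per timestep and carries membrane state between timesteps.
``conv2d_td`` is the stateless time-distributed convolution used for purely
spatial layers.

Also provided: temporal aggregation (sum / mean over the time axis) and the
running accumulator that replaces it in external-iteration (timestep-driven)
execution, where the full time axis is never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .errors import ContractError, PlanError
from .lifplus import LifPlusConfig, lifplus_step
from .neurons import NeuronParams, NeuronState, neuron_step

__all__ = [
    "STTensorSpec",
    "BlockConfig",
    "AccumulatorState",
    "build_block",
    "temporal_aggregate",
    "accumulator_step",
    "accumulator_final",
]


@dataclass(frozen=True)
class STTensorSpec:
    """Shape of an ST tensor [B, T, C, H, W]; 1-D signals use h = w = 1."""

    b: int
    t: int
    c: int
    h: int = 1
    w: int = 1

    def __post_init__(self):
        if min(self.b, self.t, self.c, self.h, self.w) < 1:
            raise ContractError("ST tensor extents must be positive")

    @property
    def shape(self):
        return (self.b, self.t, self.c, self.h, self.w)


_BLOCK_KINDS = ("conv_lif", "conv_liaf", "fc_lif", "fc_liaf", "conv2d_td")
_TEMPORAL_KINDS = ("subsample_t", "sumpool_t")


@dataclass
class BlockConfig:
    """Declarative description of one ST block (or temporal transform).

    For convolutional kinds ``in_channels``/``out_channels`` are channel
    counts and ``kernel`` the 2-D kernel extent; for fully connected kinds
    they are feature widths.  ``factor`` applies only to the temporal
    transforms ``subsample_t``/``sumpool_t`` (internal iteration only).
    """

    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: tuple[int, int] = (3, 3)
    stride: tuple[int, int] = (1, 1)
    padding: str = "same"
    norm: str = "none"
    neuron: Optional[NeuronParams] = None
    lifplus: Optional[LifPlusConfig] = None
    factor: int = 1

    def __post_init__(self):
        if self.kind not in _BLOCK_KINDS + _TEMPORAL_KINDS:
            raise PlanError(f"unknown block kind {self.kind!r}")
        if self.kind in _TEMPORAL_KINDS:
            if self.factor < 1:
                raise PlanError("temporal transform factor must be >= 1")
            return
        if self.in_channels < 1 or self.out_channels < 1:
            raise PlanError("channel/feature counts must be positive")
        if self.kind.startswith("conv") and min(self.kernel) < 1:
            raise PlanError("kernel extents must be positive")
        if self.kind == "conv2d_td" and self.neuron is not None:
            raise PlanError("conv2d_td is stateless and takes no neuron")
        if self.norm not in ("none", "batchnorm"):
            raise PlanError(f"unknown norm {self.norm!r}")

    def default_neuron(self) -> Optional[NeuronParams]:
        if self.kind == "conv2d_td":
            return None
        if self.neuron is not None:
            return self.neuron
        fire = "analog" if self.kind.endswith("liaf") else "spike"
        return NeuronParams(alpha=0.7, beta=0.0, v_th=1.0, fire_mode=fire)


class BatchNorm:
    """Per-channel batch normalization (homeostasis).

    Training statistics pool over batch, time, and space; inference uses the
    running estimates so that step-wise (external-iteration) execution
    matches sequence-wise execution exactly.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def parameters(self):
        return [self.gamma, self.beta]

    def _param_shape(self, ndim, channel_axis):
        shape = [1] * ndim
        shape[channel_axis] = -1
        return tuple(shape)

    def __call__(self, x: Tensor, train: bool, channel_axis: int) -> Tensor:
        axes = tuple(a for a in range(x.ndim) if a != channel_axis)
        pshape = self._param_shape(x.ndim, channel_axis)
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xn = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean.reshape(pshape)
            var = self.running_var.reshape(pshape)
            xn = (x - mu) / np.sqrt(var + self.eps)
        return xn * self.gamma.reshape(pshape) + self.beta.reshape(pshape)


class Block:
    """Base class: a stateful single-step layer with a sequence wrapper."""

    stateful = True

    def __init__(self, cfg: BlockConfig):
        self.cfg = cfg
        self.norm = None
        self.neuron = cfg.default_neuron()
        self.lifplus = cfg.lifplus

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def synapse_parameters(self) -> list[Tensor]:
        """Synaptic weight tensors only (excludes normalization params)."""
        raise NotImplementedError

    def init_state(self, batch: int) -> Optional[NeuronState]:
        raise NotImplementedError

    def _synapse(self, x: Tensor) -> Tensor:
        raise NotImplementedError

    def _dynamics(self, drive: Tensor, state: NeuronState):
        if self.lifplus is not None:
            return lifplus_step(state, drive, self.neuron, self.lifplus)
        return neuron_step(state, drive, self.neuron)

    def step(self, x_t: Tensor, state, train: bool = False):
        """Process one frame; returns (output, new_state)."""
        drive = self._synapse(Tensor.as_tensor(x_t))
        if self.norm is not None:
            drive = self.norm(drive, train=train, channel_axis=1)
        if self.neuron is None:
            return drive, state
        return self._dynamics(drive, state)

    def forward_sequence(self, x: Tensor, train: bool = False) -> Tensor:
        """Internal-iteration wrapper: reset, loop own timesteps, restack.

        When training with batchnorm, normalization statistics pool over
        batch and time, so the synaptic pass runs for the whole sequence
        before the neural dynamics loop.
        """
        x = Tensor.as_tensor(x)
        t_total = x.shape[1]
        state = self.init_state(x.shape[0])
        if train and self.norm is not None:
            drives = [self._synapse(x[:, t]) for t in range(t_total)]
            seq = T.stack_time(drives)
            seq = self.norm(seq, train=True, channel_axis=2)
            outs = []
            for t in range(t_total):
                if self.neuron is None:
                    outs.append(seq[:, t])
                else:
                    y, state = self._dynamics(seq[:, t], state)
                    outs.append(y)
            return T.stack_time(outs)
        outs = []
        for t in range(t_total):
            y, state = self.step(x[:, t], state, train=train)
            outs.append(y)
        return T.stack_time(outs)


class ConvBlock(Block):
    """Convolutional ST block: conv2d -> (batchnorm) -> LIF/LIAF dynamics."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__(cfg)
        k, c = cfg.in_channels, cfg.out_channels
        i, j = cfg.kernel
        fan_in = k * i * j
        self.w = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c, k, i, j)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c), requires_grad=True)
        if cfg.norm == "batchnorm":
            self.norm = BatchNorm(c)
        if self.neuron is not None:
            self.neuron.validate_channels(c)
        self.stateful = self.neuron is not None

    def parameters(self):
        ps = [self.w, self.b]
        if self.norm is not None:
            ps += self.norm.parameters()
        if self.lifplus is not None and isinstance(
            self.lifplus.stage_params.get("alpha_learn"), Tensor
        ):
            ps.append(self.lifplus.stage_params["alpha_learn"])
        return ps

    def synapse_parameters(self):
        return [self.w, self.b]

    def out_shape(self, h: int, w: int):
        if self.cfg.padding == "same":
            return -(-h // self.cfg.stride[0]), -(-w // self.cfg.stride[1])
        i, j = self.cfg.kernel
        return (
            (h - i) // self.cfg.stride[0] + 1,
            (w - j) // self.cfg.stride[1] + 1,
        )

    def init_state(self, batch: int):
        if self.neuron is None:
            return None
        if not hasattr(self, "_spatial"):
            raise PlanError("conv block spatial shape unresolved; run via a plan")
        h, w = self._spatial
        return NeuronState.zeros((batch, self.cfg.out_channels, h, w))

    def bind_spatial(self, h: int, w: int):
        self._spatial = self.out_shape(h, w)
        return self._spatial

    def _synapse(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ContractError(
                f"conv block expects [B,{self.cfg.in_channels},H,W], got {x.shape}"
            )
        return T.conv2d(x, self.w, self.b, self.cfg.stride, self.cfg.padding)


class FCBlock(Block):
    """Fully connected ST block: linear -> (batchnorm) -> dynamics.

    Inputs with spatial axes are flattened to [B, S] first, so an FC block
    can directly follow a convolutional stack.
    """

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__(cfg)
        s_in, s_out = cfg.in_channels, cfg.out_channels
        self.w = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / s_in), size=(s_out, s_in)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(s_out), requires_grad=True)
        if cfg.norm == "batchnorm":
            self.norm = BatchNorm(s_out)
        if self.neuron is not None:
            self.neuron.validate_channels(s_out)
        self.stateful = self.neuron is not None

    def parameters(self):
        ps = [self.w, self.b]
        if self.norm is not None:
            ps += self.norm.parameters()
        return ps

    def synapse_parameters(self):
        return [self.w, self.b]

    def init_state(self, batch: int):
        if self.neuron is None:
            return None
        return NeuronState.zeros((batch, self.cfg.out_channels))

    def _synapse(self, x: Tensor) -> Tensor:
        if x.ndim > 2:
            x = x.reshape(x.shape[0], -1)
        if x.shape[1] != self.cfg.in_channels:
            raise ContractError(
                f"fc block expects {self.cfg.in_channels} features, got {x.shape[1]}"
            )
        return T.linear(x, self.w, self.b)


def build_block(cfg: BlockConfig, rng: np.random.Generator) -> Block:
    if cfg.kind in _TEMPORAL_KINDS:
        raise PlanError("temporal transforms are handled by the network plan")
    if cfg.kind.startswith("conv"):
        return ConvBlock(cfg, rng)
    return FCBlock(cfg, rng)


# ---------------------------------------------------------------------------
# temporal aggregation and the external-iteration accumulator


def temporal_aggregate(x, mode: str = "sum"):
    """Aggregate an ST tensor over its time axis (axis 1).

    The sum is accumulated sequentially in timestep order so that it equals
    the running-accumulator output bitwise.
    """
    x = Tensor.as_tensor(x)
    if x.ndim < 2 or x.shape[1] < 1:
        raise ContractError("temporal_aggregate needs a non-empty time axis")
    if mode not in ("sum", "mean"):
        raise ContractError(f"unknown aggregation mode {mode!r}")
    acc = x[:, 0]
    for t in range(1, x.shape[1]):
        acc = acc + x[:, t]
    if mode == "mean":
        acc = acc / float(x.shape[1])
    return acc


@dataclass
class AccumulatorState:
    """Running sum over timesteps: Acc(i) = Acc(i-1) + Input(i), Acc(-1) = 0."""

    acc: Optional[Tensor] = None
    count: int = 0


def accumulator_step(state: AccumulatorState, x_t) -> AccumulatorState:
    x_t = Tensor.as_tensor(x_t)
    acc = x_t if state.acc is None else state.acc + x_t
    return AccumulatorState(acc=acc, count=state.count + 1)


def accumulator_final(state: AccumulatorState) -> Tensor:
    if state.acc is None:
        raise ContractError("accumulator_final before any accumulator_step")
    return state.acc
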