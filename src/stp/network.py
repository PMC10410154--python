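"""Network plans and the two timestep-iteration modes.

Internal iteration (IIM) wraps each ST block in its own time loop: every
block consumes the full [B, T, ...] sequence, resets its state, iterates its
timesteps, and emits a sequence for the next block.  This is the natural
form for BPTT training and allows per-block temporal transforms
(subsampling or sum-pooling over T between blocks).

External iteration (EIM) places the single time loop outside the network:
at each timestep one frame flows through all blocks, matching
timestep-driven neuromorphic execution.  Temporal aggregation is replaced
by a running accumulator so the time axis is never materialised.

For a plan with a shared T and no inter-block temporal transforms the two
modes perform the same arithmetic in the same order, so their outputs are
bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .blocks import (
    AccumulatorState,
    Block,
    BlockConfig,
    ConvBlock,
    accumulator_final,
    accumulator_step,
    build_block,
    temporal_aggregate,
)
from .errors import ContractError, PlanError, StaleStateError

__all__ = ["HeadSpec", "NetworkPlan", "Network", "build_network",
           "run_iim", "run_eim", "reset_states"]

_TEMPORAL_KINDS = ("subsample_t", "sumpool_t")


@dataclass
class HeadSpec:
    """Classifier head applied after temporal aggregation.

    ``linear`` is a fully connected readout; ``population`` groups the last
    layer's neurons into ``n_per_category`` neurons per category and scores
    each category by its population mean (population coding); ``none``
    returns the aggregated features unchanged.
    """

    kind: str = "linear"
    n_classes: int = 0
    n_per_category: int = 1

    def __post_init__(self):
        if self.kind not in ("linear", "population", "none"):
            raise PlanError(f"unknown head kind {self.kind!r}")
        if self.kind != "none" and self.n_classes < 1:
            raise PlanError("head needs n_classes >= 1")


@dataclass
class NetworkPlan:
    """Ordered block stack + aggregation + head + iteration mode."""

    blocks: list[BlockConfig]
    input_shape: tuple  # (C, H, W) for frames, (S,) for 1-D signals
    t_total: int
    head: Optional[HeadSpec] = None
    aggregation: str = "sum"  # sum | mean | accumulator | last_step
    mode: str = "iim"

    def __post_init__(self):
        if self.mode not in ("iim", "eim"):
            raise PlanError(f"unknown iteration mode {self.mode!r}")
        if self.aggregation not in ("sum", "mean", "accumulator", "last_step"):
            raise PlanError(f"unknown aggregation {self.aggregation!r}")
        if self.t_total < 1:
            raise PlanError("t_total must be >= 1")
        if self.mode == "eim" and self.has_temporal_transforms:
            raise PlanError(
                "external iteration requires a single shared T: "
                "temporal transforms are internal-iteration only"
            )

    @property
    def has_temporal_transforms(self) -> bool:
        return any(b.kind in _TEMPORAL_KINDS for b in self.blocks)


class _LinearHead:
    def __init__(self, in_features: int, n_classes: int, rng):
        self.w = Tensor(
            rng.normal(0.0, np.sqrt(1.0 / in_features), (n_classes, in_features)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(n_classes), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim > 2:
            x = x.reshape(x.shape[0], -1)
        return T.linear(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class _PopulationHead:
    def __init__(self, n_classes: int, n_per_category: int):
        self.n_classes = n_classes
        self.n = n_per_category

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim > 2:
            x = x.reshape(x.shape[0], -1)
        if x.shape[1] != self.n_classes * self.n:
            raise ContractError(
                f"population head expects {self.n_classes * self.n} features "
                f"({self.n_classes} categories x {self.n}), got {x.shape[1]}"
            )
        return x.reshape(x.shape[0], self.n_classes, self.n).mean(axis=2)

    def parameters(self):
        return []


class Network:
    """A built (parameterised) network executable in either iteration mode."""

    def __init__(self, plan: NetworkPlan, seed: int = 0):
        self.plan = plan
        self.training = False
        rng = np.random.default_rng(seed)
        self.entries: list = []  # Block instances or ("subsample_t"/"sumpool_t", k)
        shape = tuple(plan.input_shape)
        for cfg in plan.blocks:
            if cfg.kind in _TEMPORAL_KINDS:
                self.entries.append((cfg.kind, cfg.factor))
                continue
            if cfg.kind.startswith("conv"):
                if len(shape) != 3:
                    raise PlanError(
                        f"conv block {cfg.kind} needs a [C,H,W] input, got {shape}"
                    )
                if cfg.in_channels != shape[0]:
                    raise PlanError(
                        f"block {cfg.kind}: in_channels {cfg.in_channels} != "
                        f"incoming channels {shape[0]}"
                    )
                blk = build_block(cfg, rng)
                h, w = blk.bind_spatial(shape[1], shape[2])
                shape = (cfg.out_channels, h, w)
            else:
                feats = int(np.prod(shape))
                if cfg.in_channels != feats:
                    raise PlanError(
                        f"block {cfg.kind}: in_channels {cfg.in_channels} != "
                        f"incoming features {feats}"
                    )
                blk = build_block(cfg, rng)
                shape = (cfg.out_channels,)
            self.entries.append(blk)
        self.out_shape = shape
        self.head = self._build_head(rng)
        self._states: Optional[list] = None
        self._acc: Optional[AccumulatorState] = None
        self._last_y: Optional[Tensor] = None
        self._steps_done = 0
        self._dirty = False
        self._sample_id = None

    def _build_head(self, rng):
        spec = self.plan.head
        if spec is None or spec.kind == "none":
            return None
        feats = int(np.prod(self.out_shape))
        if spec.kind == "linear":
            return _LinearHead(feats, spec.n_classes, rng)
        return _PopulationHead(spec.n_classes, spec.n_per_category)

    @property
    def blocks(self) -> list[Block]:
        return [e for e in self.entries if isinstance(e, Block)]

    def parameters(self) -> list[Tensor]:
        ps = []
        for b in self.blocks:
            ps += b.parameters()
        if self.head is not None:
            ps += self.head.parameters()
        return ps

    # -- state handling ------------------------------------------------------
    def reset_states(self):
        """Restore every neuron state and the accumulator to initial values."""
        self._states = None
        self._acc = None
        self._last_y = None
        self._steps_done = 0
        self._dirty = False
        self._sample_id = None

    def _ensure_states(self, batch: int):
        if self._states is None:
            self._states = [b.init_state(batch) for b in self.blocks]
            self._acc = AccumulatorState()
            self._steps_done = 0

    # -- internal iteration ---------------------------------------------------
    def run_iim(self, x, train: bool = False) -> Tensor:
        """Run block-by-block over the full sequence; aggregate; classify."""
        x = Tensor.as_tensor(x)
        if x.shape[1] != self.plan.t_total:
            raise ContractError(
                f"input has T={x.shape[1]}, plan expects {self.plan.t_total}"
            )
        seq = x
        for entry in self.entries:
            if isinstance(entry, tuple):
                kind, k = entry
                seq = _temporal_transform(seq, kind, k)
            else:
                seq = entry.forward_sequence(seq, train=train)
        return self._readout_sequence(seq)

    def _readout_sequence(self, seq: Tensor) -> Tensor:
        agg = self.plan.aggregation
        if agg == "last_step":
            out = seq[:, seq.shape[1] - 1]
        elif agg == "mean":
            out = temporal_aggregate(seq, "mean")
        else:  # sum and its external-iteration form, the accumulator
            out = temporal_aggregate(seq, "sum")
        return out if self.head is None else self.head(out)

    # -- external iteration ---------------------------------------------------
    def run_eim(
        self,
        frames,
        reset: bool = True,
        sample_id=None,
    ) -> Tensor:
        """Invoke the single-step network T times and read out the result.

        ``frames`` is an ST tensor [B, T, ...] or an iterable of [B, ...]
        frames.  With ``reset=True`` (batch mode) states are reset before the
        first frame; with ``reset=False`` the caller manages resets and a new
        ``sample_id`` on stale state raises :class:`StaleStateError`.
        """
        if self.plan.has_temporal_transforms:
            raise PlanError("plan with temporal transforms cannot run in EIM")
        if reset:
            self.reset_states()
        elif self._dirty and sample_id is not None and sample_id != self._sample_id:
            raise StaleStateError(
                f"states carry sample {self._sample_id!r}; reset before "
                f"running sample {sample_id!r}"
            )
        self._sample_id = sample_id
        if isinstance(frames, (Tensor, np.ndarray)):
            frames = Tensor.as_tensor(frames)
            frames = [frames[:, t] for t in range(frames.shape[1])]
        out = None
        for frame in frames:
            out = self.step_frame(frame)
        if out is None:
            raise ContractError("run_eim needs at least one frame")
        return out

    def step_frame(self, frame) -> Tensor:
        """Process one frame through all blocks; returns the current readout."""
        frame = Tensor.as_tensor(frame)
        self._ensure_states(frame.shape[0])
        self._dirty = True
        y = frame
        for i, blk in enumerate(self.blocks):
            y, self._states[i] = blk.step(y, self._states[i], train=False)
        self._last_y = y
        self._steps_done += 1
        agg = self.plan.aggregation
        if agg == "last_step":
            out = y
        else:
            self._acc = accumulator_step(self._acc, y)
            out = accumulator_final(self._acc)
            if agg == "mean" and self._steps_done == self.plan.t_total:
                out = out / float(self.plan.t_total)
        return out if self.head is None else self.head(out)

    # -- convenience -----------------------------------------------------------
    def forward(self, x, train: bool = False) -> Tensor:
        return self.run_iim(x, train=train)


def _temporal_transform(seq: Tensor, kind: str, k: int) -> Tensor:
    t = seq.shape[1]
    if kind == "subsample_t":
        return T.stack_time([seq[:, tt] for tt in range(0, t, k)])
    if t % k != 0:
        raise PlanError(f"sumpool_t factor {k} does not divide T={t}")
    groups = []
    for g in range(t // k):
        acc = seq[:, g * k]
        for o in range(1, k):
            acc = acc + seq[:, g * k + o]
        groups.append(acc)
    return T.stack_time(groups)


def build_network(plan: NetworkPlan, seed: int = 0) -> Network:
    return Network(plan, seed=seed)


def save_checkpoint(net: Network, path) -> None:
    """Write all parameters and normalization statistics to a .npz archive."""
    arrays = {f"p{i}": p.data for i, p in enumerate(net.parameters())}
    j = 0
    for b in net.blocks:
        if b.norm is not None:
            arrays[f"bn{j}_mean"] = b.norm.running_mean
            arrays[f"bn{j}_var"] = b.norm.running_var
            j += 1
    np.savez(path, **arrays)


def load_checkpoint(net: Network, path) -> Network:
    """Restore a checkpoint written by :func:`save_checkpoint` in place."""
    with np.load(path) as data:
        for i, p in enumerate(net.parameters()):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise PlanError(
                    f"checkpoint parameter {i} shape {arr.shape} != {p.data.shape}"
                )
            p.data = arr
        j = 0
        for b in net.blocks:
            if b.norm is not None:
                b.norm.running_mean = data[f"bn{j}_mean"]
                b.norm.running_var = data[f"bn{j}_var"]
                j += 1
    return net


# -- module-level functional forms -------------------------------------------


def run_iim(net: Network, x, train: bool = False) -> Tensor:
    """Internal-iteration forward pass (time loop inside each block)."""
    return net.run_iim(x, train=train)


def run_eim(net: Network, frames, **kw) -> Tensor:
    """External-iteration forward pass (time loop outside the network)."""
    return net.run_eim(frames, **kw)


def reset_states(net: Network) -> None:
    """Reset all neuron and accumulator states to their initial values."""
    net.reset_states()
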