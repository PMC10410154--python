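"""Generalized local synaptic plasticity (Hebb / STDP / R-STDP).

Plasticity acts on one selected synaptic array (by default the weights of
the network's last fully connected spiking layer) and is driven purely by
locally available signals: presynaptic and postsynaptic spikes, their
exponentially decaying traces

    t_in/out <- theta * t_in/out + eta * S_in/out,

and, for the reward-modulated rule, an error-derived reward.  The trace
form of STDP is

    dW[i, j] = t_in[i] * S_out[j] - S_in[i] * t_out[j],

an outer-product update: a postsynaptic spike arriving while the
presynaptic trace is alive potentiates the synapse, a presynaptic spike
arriving while the postsynaptic trace is alive depresses it.  R-STDP
multiplies each output neuron's column by its reward before the learning
step ``w <- w + lr * dw``.

The reward uses population coding: each category is represented by
``n_per_category`` output neurons, a category's activity is the mean output
of its population, and the reward is the one-hot label minus that mean,
broadcast back to the category's neurons.

Per-timestep order of operations (documented so toy simulations are
reproducible): (1) update both traces with the current spikes, (2) compute
dW, (3) apply.  Two simultaneous single spikes therefore cancel exactly
with theta=0, eta=1.

Co-learning alternates global phases (BPTT with plasticity detached) and
local phases (all other weights frozen; plasticity streamed per sample at
batch size one, updating at every timestep).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from ._tensor import Tensor, no_grad
from .blocks import FCBlock
from .errors import ContractError, PlanError
from .network import Network
from .training import TrainConfig, bptt_train, evaluate

__all__ = [
    "PlasticityState",
    "RewardSpec",
    "PlasticityRule",
    "update_traces",
    "stdp_delta",
    "hebb_delta",
    "compute_reward",
    "apply_update",
    "co_learning_schedule",
    "register_rule",
    "LocalPhase",
    "GlobalPhase",
]


@dataclass
class PlasticityState:
    """Pre/post spike traces plus the rule's scalar knobs."""

    t_in: np.ndarray
    t_out: np.ndarray
    theta: float = 0.95  # trace decay
    eta: float = 1.0  # trace gain
    lr: float = 0.001

    @classmethod
    def zeros(cls, n_in: int, n_out: int, **kw) -> "PlasticityState":
        return cls(t_in=np.zeros(n_in), t_out=np.zeros(n_out), **kw)


@dataclass(frozen=True)
class RewardSpec:
    """Population-coded reward: ``n_per_category`` neurons per category."""

    n_per_category: int
    n_categories: int
    label: np.ndarray  # one-hot over categories

    def __post_init__(self):
        label = np.asarray(self.label, dtype=np.float64)
        if label.shape != (self.n_categories,):
            raise ContractError("label must be a one-hot vector over categories")
        object.__setattr__(self, "label", label)

    @property
    def width(self) -> int:
        return self.n_per_category * self.n_categories


def update_traces(ps: PlasticityState, s_in, s_out) -> PlasticityState:
    """t <- theta*t + eta*S, elementwise on both sides."""
    s_in = np.asarray(s_in, dtype=np.float64)
    s_out = np.asarray(s_out, dtype=np.float64)
    if s_in.shape != ps.t_in.shape or s_out.shape != ps.t_out.shape:
        raise ContractError("spike/trace shape mismatch")
    return replace(
        ps,
        t_in=ps.theta * ps.t_in + ps.eta * s_in,
        t_out=ps.theta * ps.t_out + ps.eta * s_out,
    )


def stdp_delta(ps: PlasticityState, s_in, s_out) -> np.ndarray:
    """dW[i, j] = t_in[i]*S_out[j] - S_in[i]*t_out[j] (traces already
    updated for this timestep)."""
    s_in = np.asarray(s_in, dtype=np.float64)
    s_out = np.asarray(s_out, dtype=np.float64)
    if s_in.shape != ps.t_in.shape or s_out.shape != ps.t_out.shape:
        raise ContractError("spike/trace shape mismatch")
    return np.outer(ps.t_in, s_out) - np.outer(s_in, ps.t_out)


def hebb_delta(ps: PlasticityState, s_in, s_out) -> np.ndarray:
    """Plain Hebbian coincidence: dW[i, j] = S_in[i] * S_out[j]."""
    return np.outer(np.asarray(s_in, dtype=np.float64),
                    np.asarray(s_out, dtype=np.float64))


def compute_reward(spikes_out, spec: RewardSpec) -> np.ndarray:
    """Per-output-neuron reward r = L - O, O the category population mean.

    Accepts any spike-like output vector (instantaneous spikes or rates) of
    width ``n_per_category * n_categories``; the reward is constant across
    the neurons of one category and zero exactly when every population mean
    equals its label entry.
    """
    o = np.asarray(spikes_out, dtype=np.float64).ravel()
    if o.shape != (spec.width,):
        raise ContractError(
            f"output width {o.shape} != {spec.n_categories} categories x "
            f"{spec.n_per_category} neurons"
        )
    o_cat = o.reshape(spec.n_categories, spec.n_per_category).mean(axis=1)
    r_cat = spec.label - o_cat
    return np.repeat(r_cat, spec.n_per_category)


def apply_update(
    w: np.ndarray,
    dw: np.ndarray,
    reward: Optional[np.ndarray],
    ps: PlasticityState,
) -> np.ndarray:
    """w <- w + lr * dw, with dw's output columns scaled by the reward when
    one is given (R-STDP).  ``w`` and ``dw`` are [n_in, n_out]."""
    if w.shape != dw.shape:
        raise ContractError("dW shape must equal W shape")
    if reward is not None:
        dw = dw * np.asarray(reward)[None, :]
    return w + ps.lr * dw


@dataclass(frozen=True)
class PlasticityRule:
    """A named update rule SP: (spikes, traces, reward, W) -> dW."""

    kind: str
    fn: Callable


def _rule_stdp(ps, s_in, s_out, reward, w):
    return stdp_delta(ps, s_in, s_out)


def _rule_r_stdp(ps, s_in, s_out, reward, w):
    dw = stdp_delta(ps, s_in, s_out)
    return dw * np.asarray(reward)[None, :]


def _rule_hebb(ps, s_in, s_out, reward, w):
    return hebb_delta(ps, s_in, s_out)


RULES: dict[str, PlasticityRule] = {
    "stdp": PlasticityRule("stdp", _rule_stdp),
    "r_stdp": PlasticityRule("r_stdp", _rule_r_stdp),
    "hebb": PlasticityRule("hebb", _rule_hebb),
}


def register_rule(name: str, fn: Callable):
    """Register a custom plasticity rule under ``name``."""
    RULES[name] = PlasticityRule(name, fn)


# ---------------------------------------------------------------------------
# co-learning schedule


@dataclass
class GlobalPhase:
    train: TrainConfig


@dataclass
class LocalPhase:
    rule: str = "r_stdp"
    lr: float = 0.001
    theta: float = 0.95
    eta: float = 1.0
    passes: int = 1
    target_layer: Optional[int] = None  # block index; default: last FC block


def _resolve_target(net: Network, phase: LocalPhase) -> int:
    if phase.target_layer is not None:
        idx = phase.target_layer
        if not isinstance(net.blocks[idx], FCBlock):
            raise PlanError("local phase target must be a fully connected block")
        return idx
    for i in range(len(net.blocks) - 1, -1, -1):
        if isinstance(net.blocks[i], FCBlock) and net.blocks[i].neuron is not None:
            return i
    raise PlanError("no fully connected spiking layer to fine-tune")


def _reward_spec(net: Network, label: int) -> RewardSpec:
    head = net.plan.head
    if head is None or head.kind != "population":
        raise PlanError("reward-modulated fine-tuning needs a population head")
    onehot = np.zeros(head.n_classes)
    onehot[label] = 1.0
    return RewardSpec(head.n_per_category, head.n_classes, onehot)


def _stream_sample(net, x_t_seq, label, ti, target, phase, rule):
    """Stream one sample (batch of one) through the network, updating the
    target weights at every timestep; for r_stdp the reward is recomputed
    each timestep from the current output spikes against the label."""
    spec = _reward_spec(net, label) if phase.rule == "r_stdp" else None
    ps = PlasticityState.zeros(
        target.cfg.in_channels, target.cfg.out_channels,
        theta=phase.theta, eta=phase.eta, lr=phase.lr,
    )
    states = [b.init_state(1) for b in net.blocks]
    w = target.w.data.T.copy()  # [n_in, n_out]
    for t in range(x_t_seq.shape[0]):
        yt = Tensor(x_t_seq[t][None])
        s_in = s_out = None
        for i, blk in enumerate(net.blocks):
            if i == ti:
                s_in = yt.data.reshape(-1)
            yt, states[i] = blk.step(yt, states[i])
            if i == ti:
                s_out = yt.data.reshape(-1)
        ps = update_traces(ps, s_in, s_out)
        reward = compute_reward(s_out, spec) if spec is not None else None
        dw = rule.fn(ps, s_in, s_out, reward, w)
        w = w + ps.lr * dw
        target.w.data = w.T  # streamed: next timestep sees the update


def co_learning_schedule(net: Network, phases, train_set, val_set=None):
    """Alternate global (BPTT) and local (plasticity) phases on a network.

    ``phases`` is an ordered list of :class:`GlobalPhase` /
    :class:`LocalPhase`.  During global phases plasticity is detached;
    during local phases every weight except the target synaptic array is
    frozen.  Returns a list of per-phase summaries.
    """
    log = []
    for k, phase in enumerate(phases):
        if isinstance(phase, GlobalPhase):
            metrics = bptt_train(net, train_set, phase.train, val_set=val_set)
            log.append({"phase": k, "kind": "global", "metrics": metrics})
        elif isinstance(phase, LocalPhase):
            rule = RULES.get(phase.rule)
            if rule is None:
                raise ContractError(
                    f"unknown rule {phase.rule!r}; known: {sorted(RULES)}"
                )
            ti = _resolve_target(net, phase)
            target = net.blocks[ti]
            x = np.asarray(train_set.x if hasattr(train_set, "x") else train_set[0])
            y = np.asarray(train_set.y if hasattr(train_set, "y") else train_set[1])
            rng = np.random.default_rng(getattr(phase, "seed", 0))
            with no_grad():
                for _ in range(phase.passes):
                    for n in rng.permutation(len(y)):
                        _stream_sample(net, x[n], int(y[n]), ti, target, phase, rule)
            row = {"phase": k, "kind": "local", "rule": phase.rule}
            if val_set is not None:
                row["val_acc"] = evaluate(net, val_set)
            log.append(row)
        else:
            raise ContractError("phases must be GlobalPhase or LocalPhase")
    return log
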