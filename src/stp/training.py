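"""Global learning: surrogate-gradient BPTT over network plans.

Training unrolls the time loop of the internal-iteration forward pass and
backpropagates through both the surrogate spike derivatives and the
membrane-potential recurrence.  States are recreated at every sample
boundary, so no gradient flows between samples.

Optional half-precision training runs the forward/backward pass in float16
with the loss amplified by ``loss_scale`` (default 512); gradients are
de-amplified before the update and a non-finite gradient triggers a
loss-scale backoff (halve and skip the step).  Master weights stay in
float64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor, no_grad
from .errors import ContractError
from .network import Network

__all__ = ["TrainConfig", "bptt_train", "evaluate"]


@dataclass
class TrainConfig:
    optimizer: str = "adam"  # "adam" | "sgd" (with momentum)
    lr: float = 1e-3
    weight_decay: float = 1e-4
    momentum: float = 0.9
    schedule: str = "none"  # "none" | "cosine" | "step"
    step_size: int = 10
    step_gamma: float = 0.1
    epochs: int = 20
    batch_size: int = 20
    half_precision: bool = False
    loss_scale: float = 512.0
    seed: int = 0

    def __post_init__(self):
        if self.lr < 0:
            raise ContractError("lr must be >= 0")
        if self.loss_scale < 1:
            raise ContractError("loss_scale must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ContractError(f"unknown optimizer {self.optimizer!r}")
        if self.schedule not in ("none", "cosine", "step"):
            raise ContractError(f"unknown schedule {self.schedule!r}")


class _SGD:
    def __init__(self, params, cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.vel = [np.zeros_like(p.data) for p in params]

    def step(self, lr):
        for p, v in zip(self.params, self.vel):
            g = p.grad + self.cfg.weight_decay * p.data
            v *= self.cfg.momentum
            v += g
            p.data = p.data - lr * v


class _Adam:
    def __init__(self, params, cfg: TrainConfig, eps=1e-8, b1=0.9, b2=0.999):
        self.params = params
        self.cfg = cfg
        self.eps, self.b1, self.b2 = eps, b1, b2
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.cfg.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p.data = p.data - lr * mh / (np.sqrt(vh) + self.eps)


def _epoch_lr(cfg: TrainConfig, epoch: int) -> float:
    if cfg.schedule == "cosine":
        return cfg.lr * 0.5 * (1 + np.cos(np.pi * epoch / max(cfg.epochs, 1)))
    if cfg.schedule == "step":
        return cfg.lr * cfg.step_gamma ** (epoch // cfg.step_size)
    return cfg.lr


def _as_xy(dataset):
    if hasattr(dataset, "x") and hasattr(dataset, "y"):
        if dataset.x is None:
            raise ContractError("dataset has no tensor representation")
        return np.asarray(dataset.x), np.asarray(dataset.y)
    x, y = dataset
    return np.asarray(x), np.asarray(y)


def evaluate(net: Network, dataset, batch_size: int = 64) -> float:
    """Top-1 accuracy of the network over a labeled dataset."""
    x, y = _as_xy(dataset)
    if len(y) == 0:
        raise ContractError("cannot evaluate on an empty dataset")
    correct = 0
    with no_grad():
        for lo in range(0, len(y), batch_size):
            out = net.run_iim(Tensor(x[lo : lo + batch_size]))
            correct += int((out.data.argmax(axis=1) == y[lo : lo + batch_size]).sum())
    return correct / len(y)


def bptt_train(net: Network, train_set, cfg: TrainConfig, val_set=None):
    """Train a network with surrogate-gradient BPTT.

    Returns a list of per-epoch metric dicts (loss, train/val accuracy,
    learning rate).  Deterministic given ``cfg.seed`` and the network's
    initialisation seed.
    """
    x, y = _as_xy(train_set)
    params = net.parameters()
    opt = (_Adam if cfg.optimizer == "adam" else _SGD)(params, cfg)
    rng = np.random.default_rng(cfg.seed)
    loss_scale = cfg.loss_scale if cfg.half_precision else 1.0
    metrics = []
    net.training = True
    try:
        for epoch in range(cfg.epochs):
            lr = _epoch_lr(cfg, epoch)
            order = rng.permutation(len(y))
            losses, correct = [], 0
            for lo in range(0, len(y), cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                if cfg.half_precision:
                    masters = [p.data for p in params]
                    for p in params:
                        p.data = p.data.astype(np.float16)
                    xb = xb.astype(np.float16)
                out = net.run_iim(Tensor(xb), train=True)
                loss = T.cross_entropy(out, yb)
                if not np.isfinite(loss.data) and not cfg.half_precision:
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}"
                    )
                for p in params:
                    p.zero_grad()
                (loss * loss_scale).backward()
                if cfg.half_precision:
                    for p, master in zip(params, masters):
                        p.data = master
                grads_ok = True
                for p in params:
                    if p.grad is None:
                        p.grad = np.zeros_like(p.data)
                    p.grad = np.asarray(p.grad, dtype=np.float64) / loss_scale
                    if not np.isfinite(p.grad).all():
                        grads_ok = False
                if not grads_ok:
                    if cfg.half_precision and loss_scale > 1:
                        loss_scale = max(loss_scale / 2, 1.0)  # backoff, skip step
                        continue
                    raise RuntimeError(
                        f"training diverged: non-finite gradients at epoch {epoch}"
                    )
                opt.step(lr)
                losses.append(float(loss.data))
                correct += int((out.data.argmax(axis=1) == yb).sum())
            row = {
                "epoch": epoch,
                "lr": lr,
                "loss_scale": loss_scale,
                "train_loss": float(np.mean(losses)) if losses else float("nan"),
                "train_acc": correct / len(y),
            }
            if val_set is not None:
                net.training = False
                row["val_acc"] = evaluate(net, val_set)
                net.training = True
            metrics.append(row)
    finally:
        net.training = False
    return metrics
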