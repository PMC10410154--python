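"""Unified run configuration: one structured file integrates the network
plan, the dataset/pipeline, training, and plasticity phases.

Configs are YAML; every key is validated (unknown keys are errors, never
silently ignored) and defaults are filled in, so a dumped resolved config
reloads to the same object.  All randomness in a run flows from the single
top-level ``seed``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError
from .lifplus import LifPlusConfig
from .network import HeadSpec, NetworkPlan
from .neurons import NeuronParams, SurrogateSpec
from .blocks import BlockConfig
from .synthetic import gen_synthetic_motion
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "dump_config", "to_plan",
           "to_train_config", "make_datasets"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NeuronCfg(_Model):
    alpha: float | list[float] = 0.7
    beta: float | list[float] = 0.0
    v_th: float | list[float] = 1.0
    v_reset: float | list[float] = 0.0
    r_gain: float = 1.0
    reset_mode: Literal["hard", "soft"] = "hard"
    sharing_mode: Literal["asm", "csm"] = "asm"
    activation: Literal["relu", "identity"] = "relu"
    surrogate_width: float = 1.0


class LifPlusCfg(_Model):
    a_decay: int = 0
    b_accum: int = 0
    c_trigger: int = 0
    d_inhib: int = 0
    e_refrac: int = 0
    stage_params: dict = {}


class BlockCfg(_Model):
    kind: Literal["conv_lif", "conv_liaf", "fc_lif", "fc_liaf", "conv2d_td",
                  "subsample_t", "sumpool_t"]
    in_channels: int = 0
    out_channels: int = 0
    kernel: tuple[int, int] = (3, 3)
    stride: tuple[int, int] = (1, 1)
    padding: Literal["same", "valid"] = "same"
    norm: Literal["none", "batchnorm"] = "none"
    neuron: Optional[NeuronCfg] = None
    lifplus: Optional[LifPlusCfg] = None
    factor: int = 1


class HeadCfg(_Model):
    kind: Literal["linear", "population", "none"] = "linear"
    n_classes: int = 0
    n_per_category: int = 1


class NetworkCfg(_Model):
    mode: Literal["iim", "eim"] = "iim"
    t_total: int
    input_shape: list[int]
    aggregation: Literal["sum", "mean", "accumulator", "last_step"] = "sum"
    blocks: list[BlockCfg]
    head: Optional[HeadCfg] = None


class DatasetCfg(_Model):
    kind: Literal["synthetic_motion"] = "synthetic_motion"
    classes: list[str] = ["left", "right", "up"]
    t_steps: int = 20
    hw: tuple[int, int] = (20, 20)
    n_train: int = 200
    n_val: int = 60
    emit: Literal["st", "events", "frames"] = "st"
    noise_ratio: float = 0.0
    val_noise_ratio: float = 0.0


class TrainCfg(_Model):
    optimizer: Literal["adam", "sgd"] = "adam"
    lr: float = 1e-3
    weight_decay: float = 1e-4
    momentum: float = 0.9
    schedule: Literal["none", "cosine", "step"] = "none"
    step_size: int = 10
    step_gamma: float = 0.1
    epochs: int = 20
    batch_size: int = 20
    half_precision: bool = False
    loss_scale: float = 512.0


class PhaseCfg(_Model):
    kind: Literal["global", "local"]
    rule: str = "r_stdp"
    lr: float = 0.001
    theta: float = 0.95
    eta: float = 1.0
    passes: int = 1
    target_layer: Optional[int] = None


class PlasticityCfg(_Model):
    phases: list[PhaseCfg]


class RunConfig(_Model):
    seed: int = 0
    network: NetworkCfg
    dataset: Optional[DatasetCfg] = None
    train: Optional[TrainCfg] = None
    plasticity: Optional[PlasticityCfg] = None
    output_dir: str = "scratch/run"


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; errors name the offending key."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in e.errors()
        ]
        raise ConfigError("invalid config:\n  " + "\n  ".join(lines)) from None


def dump_config(cfg: RunConfig) -> str:
    """YAML text of the fully resolved config (round-trips losslessly)."""
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False)


def _to_neuron(cfg: Optional[NeuronCfg], kind: str) -> Optional[NeuronParams]:
    if kind == "conv2d_td":
        return None
    fire = "analog" if kind.endswith("liaf") else "spike"
    if cfg is None:
        return NeuronParams(alpha=0.7, fire_mode=fire)
    as_arr = lambda v: np.asarray(v, dtype=np.float64)
    return NeuronParams(
        alpha=as_arr(cfg.alpha), beta=as_arr(cfg.beta), v_th=as_arr(cfg.v_th),
        v_reset=as_arr(cfg.v_reset), r_gain=cfg.r_gain,
        reset_mode=cfg.reset_mode, fire_mode=fire,
        sharing_mode=cfg.sharing_mode, activation=cfg.activation,
        surrogate=SurrogateSpec(width=cfg.surrogate_width),
    )


def to_plan(cfg: RunConfig) -> NetworkPlan:
    blocks = []
    for b in cfg.network.blocks:
        lifplus = None
        if b.lifplus is not None:
            lifplus = LifPlusConfig(
                b.lifplus.a_decay, b.lifplus.b_accum, b.lifplus.c_trigger,
                b.lifplus.d_inhib, b.lifplus.e_refrac,
                stage_params=dict(b.lifplus.stage_params),
            )
        blocks.append(
            BlockConfig(
                kind=b.kind, in_channels=b.in_channels,
                out_channels=b.out_channels, kernel=tuple(b.kernel),
                stride=tuple(b.stride), padding=b.padding, norm=b.norm,
                neuron=_to_neuron(b.neuron, b.kind), lifplus=lifplus,
                factor=b.factor,
            )
        )
    head = None
    if cfg.network.head is not None:
        head = HeadSpec(
            kind=cfg.network.head.kind,
            n_classes=cfg.network.head.n_classes,
            n_per_category=cfg.network.head.n_per_category,
        )
    return NetworkPlan(
        blocks=blocks,
        input_shape=tuple(cfg.network.input_shape),
        t_total=cfg.network.t_total,
        head=head,
        aggregation=cfg.network.aggregation,
        mode=cfg.network.mode,
    )


def to_train_config(cfg: RunConfig) -> TrainConfig:
    t = cfg.train or TrainCfg()
    return TrainConfig(seed=cfg.seed, **t.model_dump())


def make_datasets(cfg: RunConfig):
    """Generate (train, val) datasets from the dataset section and seed."""
    d = cfg.dataset or DatasetCfg()
    train = gen_synthetic_motion(
        classes=tuple(d.classes), t_steps=d.t_steps, hw=tuple(d.hw),
        n_samples=d.n_train, seed=cfg.seed, emit=d.emit,
        noise_ratio=d.noise_ratio,
    )
    val = gen_synthetic_motion(
        classes=tuple(d.classes), t_steps=d.t_steps, hw=tuple(d.hw),
        n_samples=d.n_val, seed=cfg.seed + 1, emit=d.emit,
        noise_ratio=d.val_noise_ratio,
    )
    return train, val
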