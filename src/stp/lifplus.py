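"""Configurable LIF variants (the "LIF+" family).

The step function is factored into five stages, each with a registry of
interchangeable modes:

A — decay:              0 fixed multiplicative+additive decay,
                        1 learnable per-channel multiplicative decay
B — spike accumulation: 0 direct current accumulation,
                        1 alpha-synapse low-pass filter,
                        2 dual-exponential synapse (decay minus rise),
                        3 instantaneous current pulse with gain
C — trigger condition:  0 fixed threshold,
                        1 adaptive threshold with spike-triggered increment,
                        2 stochastic threshold (Gaussian jitter)
D — inhibition:         0 off,
                        1 winner-take-all lateral inhibition across channels
E — refractory:         0 off,
                        1 fixed refractory period

The all-zero configuration reduces, bitwise, to the plain LIF/LIAF step.
Gating masks (inhibition, refractory) and threshold noise act as constants
in the backward pass; the synaptic filters of stage B are part of the
differentiable recurrence, so those variants train with BPTT unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, spike
from .errors import ConfigError
from .neurons import ACTIVATIONS, NeuronParams, NeuronState, _check_input, neuron_step

__all__ = ["LifPlusConfig", "lifplus_step", "REGISTERED_MODES"]

REGISTERED_MODES = {
    "a_decay": (0, 1),
    "b_accum": (0, 1, 2, 3),
    "c_trigger": (0, 1, 2),
    "d_inhib": (0, 1),
    "e_refrac": (0, 1),
}

_DEFAULT_STAGE_PARAMS = {
    "k_syn": 0.5,       # B=1 low-pass coefficient
    "k_decay": 0.8,     # B=2 decay filter coefficient
    "k_rise": 0.3,      # B=2 rise filter coefficient
    "pulse_gain": 1.0,  # B=3 pulse amplitude
    "theta_decay": 0.9,   # C=1 adaptive-threshold decay
    "theta_inc": 0.1,     # C=1 spike-triggered increment
    "noise_sigma": 0.1,   # C=2 threshold jitter std
    "noise_seed": 0,      # C=2 rng seed at state reset
    "refrac_period": 2,   # E=1 timesteps silenced after a spike
    "alpha_learn": None,  # A=1 per-channel decay (array or Tensor)
}


@dataclass
class LifPlusConfig:
    """Mode ids for the five stages plus mode-specific parameters."""

    a_decay: int = 0
    b_accum: int = 0
    c_trigger: int = 0
    d_inhib: int = 0
    e_refrac: int = 0
    stage_params: dict = field(default_factory=dict)

    def __post_init__(self):
        for stage, allowed in REGISTERED_MODES.items():
            mode = getattr(self, stage)
            if mode not in allowed:
                raise ConfigError(
                    f"unregistered {stage} mode {mode}; registered modes: {allowed}"
                )
        unknown = set(self.stage_params) - set(_DEFAULT_STAGE_PARAMS)
        if unknown:
            raise ConfigError(f"unknown stage parameters: {sorted(unknown)}")

    def param(self, name):
        return self.stage_params.get(name, _DEFAULT_STAGE_PARAMS[name])

    @property
    def is_default(self) -> bool:
        return not (
            self.a_decay or self.b_accum or self.c_trigger
            or self.d_inhib or self.e_refrac
        )

    def modes(self) -> tuple[int, int, int, int, int]:
        return (self.a_decay, self.b_accum, self.c_trigger,
                self.d_inhib, self.e_refrac)


def _aux_tensor(aux: dict, key: str, like: Tensor) -> Tensor:
    val = aux.get(key)
    if val is None:
        val = Tensor(np.zeros(like.shape))
    return val


def lifplus_step(
    state: NeuronState, input_current, params: NeuronParams, cfg: LifPlusConfig
) -> tuple[Tensor, NeuronState]:
    """One timestep of a configured LIF+ neuron layer.

    With the all-default configuration this delegates to
    :func:`stp.neurons.neuron_step` and is bitwise identical to it.
    """
    if cfg.is_default:
        return neuron_step(state, input_current, params)

    i_t = _check_input(state, input_current)
    nd = state.v.ndim
    aux = dict(state.aux)

    # stage B — synaptic accumulation
    if cfg.b_accum == 1:
        syn = _aux_tensor(aux, "syn", i_t) * cfg.param("k_syn") + i_t
        aux["syn"] = syn
        i_eff = syn
    elif cfg.b_accum == 2:
        syn_d = _aux_tensor(aux, "syn_d", i_t) * cfg.param("k_decay") + i_t
        syn_r = _aux_tensor(aux, "syn_r", i_t) * cfg.param("k_rise") + i_t
        aux["syn_d"], aux["syn_r"] = syn_d, syn_r
        i_eff = syn_d - syn_r
    elif cfg.b_accum == 3:
        i_eff = i_t * cfg.param("pulse_gain")
    else:
        i_eff = i_t

    # stage (a) of the base procedure — integrate
    r_gain = params.expand("r_gain", nd)
    if np.ndim(r_gain) == 0 and float(r_gain) == 1.0:
        v_m = state.v + i_eff
    else:
        v_m = state.v + i_eff * r_gain

    # stage C — trigger condition
    v_th_eff = params.expand("v_th", nd)
    if cfg.c_trigger == 1:
        theta = aux.get("theta")
        if theta is None:
            theta = np.zeros(state.v.shape)
        v_th_eff = v_th_eff + theta
    elif cfg.c_trigger == 2:
        rng = aux.get("rng")
        if rng is None:
            rng = np.random.default_rng(cfg.param("noise_seed"))
            aux["rng"] = rng
        v_th_eff = v_th_eff + cfg.param("noise_sigma") * rng.standard_normal(
            state.v.shape
        )

    f = spike(v_m, v_th_eff, params.surrogate.width)

    # stage D — winner-take-all lateral inhibition across the channel axis
    if cfg.d_inhib == 1:
        fired = f.data > 0
        masked = np.where(fired, v_m.data, -np.inf)
        winner = masked.argmax(axis=1, keepdims=True)
        onehot = np.zeros_like(f.data)
        np.put_along_axis(onehot, winner, 1.0, axis=1)
        f = f * (onehot * fired.any(axis=1, keepdims=True))

    # stage E — refractory gating
    if cfg.e_refrac == 1:
        period = int(cfg.param("refrac_period"))
        counters = aux.get("refrac")
        if counters is None:
            counters = np.zeros(state.v.shape, dtype=np.int64)
        counters = np.maximum(counters - 1, 0)
        gate = (counters == 0).astype(f.data.dtype)
        f = f * gate
        counters = np.where(f.data > 0, period, counters)
        aux["refrac"] = counters

    # update the adaptive threshold with the (gated) fire signal
    if cfg.c_trigger == 1:
        theta = aux.get("theta")
        if theta is None:
            theta = np.zeros(state.v.shape)
        aux["theta"] = cfg.param("theta_decay") * theta + cfg.param(
            "theta_inc"
        ) * f.data

    # stages (c)-(d) of the base procedure — reset and leak
    v_reset = params.expand("v_reset", nd)
    if params.reset_mode == "hard":
        r = f * v_reset + (1.0 - f) * v_m
    else:
        r = f * (v_m - v_th_eff) + (1.0 - f) * v_m

    # stage A — decay source
    if cfg.a_decay == 1:
        alpha = cfg.param("alpha_learn")
        if alpha is None:
            raise ConfigError("a_decay=1 requires the 'alpha_learn' stage parameter")
        if isinstance(alpha, Tensor):
            alpha = alpha.reshape((alpha.shape[0],) + (1,) * (nd - 2))
        else:
            alpha = np.reshape(alpha, (np.shape(alpha)[0],) + (1,) * (nd - 2))
        v_new = alpha * r + params.expand("beta", nd)
    else:
        v_new = params.expand("alpha", nd) * r + params.expand("beta", nd)

    y = f if params.fire_mode == "spike" else ACTIVATIONS[params.activation](v_new)
    return y, NeuronState(v=v_new, aux=aux)
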