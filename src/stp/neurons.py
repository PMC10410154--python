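"""Discrete-time leaky integrate-and-fire (LIF) neuron dynamics.

The membrane update follows the standard Euler-discretised LIF recurrence,
written as a five-step tensor procedure executed once per timestep:

(a) integrate:  ``V_m = V_prev + r * I``
(b) fire:       ``F = (V_m >= V_th)`` (inclusive at the threshold)
(c) reset:      hard  ``R = F*V_reset + (1-F)*V_m``
                soft  ``R = F*(V_m - V_th) + (1-F)*V_m``  (residual membrane
                potential, RMP)
(d) leak:       ``V = alpha * R + beta``
(e) output:     ``Y = F`` (spiking, LIF) or ``Y = f(V)`` (analog, LIAF)

``alpha`` is the multiplicative decay, ``beta`` the additive decay.  In the
analog-fire (LIAF) variant the layer transmits ``f(V)`` — an activation of
the post-leak potential — instead of the binary spike, keeping the same
membrane dynamics but an analog signal path.

Parameters are either one scalar shared by the whole layer (all-sharing
mode, ASM) or one value per channel (channel-sharing mode, CSM).

Training uses a surrogate gradient: the forward pass keeps the exact
Heaviside fire condition while the backward pass substitutes a rectangular
window of unit area centred on the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._tensor import Tensor, relu, spike
from .errors import ContractError, InvalidParameterError

__all__ = [
    "NeuronParams",
    "NeuronState",
    "ContinuousLIFParams",
    "SurrogateSpec",
    "continuous_to_discrete",
    "neuron_step",
    "surrogate_spike_grad",
]

ACTIVATIONS = {
    "relu": relu,
    "identity": lambda x: x,
}


@dataclass(frozen=True)
class SurrogateSpec:
    """Surrogate derivative used for the spike step in the backward pass.

    Only the rectangular window is implemented: height 1/width over
    ``|V_m - V_th| <= width/2``, which integrates to one.
    """

    shape: str = "rect"
    width: float = 1.0

    def __post_init__(self):
        if self.shape != "rect":
            raise InvalidParameterError(f"unknown surrogate shape {self.shape!r}")
        if self.width <= 0:
            raise InvalidParameterError("surrogate width must be > 0")


@dataclass
class NeuronParams:
    """Parameters of a discrete LIF/LIAF neuron layer.

    Scalars in all-sharing mode (ASM); 1-D arrays of length C (the channel
    count) in channel-sharing mode (CSM).  ``r_gain`` is the input-resistance
    gain; it defaults to 1 because in a network it can be folded into the
    synaptic weights.
    """

    alpha: float | np.ndarray = 1.0
    beta: float | np.ndarray = 0.0
    v_th: float | np.ndarray = 1.0
    v_reset: float | np.ndarray = 0.0
    r_gain: float | np.ndarray = 1.0
    reset_mode: str = "hard"  # "hard" | "soft" (RMP)
    fire_mode: str = "spike"  # "spike" (LIF) | "analog" (LIAF)
    sharing_mode: str = "asm"  # "asm" | "csm"
    activation: str = "relu"  # analog activation f(.), LIAF only
    surrogate: SurrogateSpec = field(default_factory=SurrogateSpec)

    def __post_init__(self):
        if self.reset_mode not in ("hard", "soft"):
            raise InvalidParameterError(f"unknown reset_mode {self.reset_mode!r}")
        if self.fire_mode not in ("spike", "analog"):
            raise InvalidParameterError(f"unknown fire_mode {self.fire_mode!r}")
        if self.sharing_mode not in ("asm", "csm"):
            raise InvalidParameterError(f"unknown sharing_mode {self.sharing_mode!r}")
        if self.activation not in ACTIVATIONS:
            raise InvalidParameterError(f"unknown activation {self.activation!r}")
        for name in ("alpha", "beta", "v_th", "v_reset", "r_gain"):
            val = np.asarray(getattr(self, name), dtype=np.float64)
            if name != "v_th" and not np.all(np.isfinite(val)):
                raise InvalidParameterError(f"{name} must be finite")
            if self.sharing_mode == "asm" and val.ndim != 0:
                raise InvalidParameterError(f"ASM requires scalar {name}")
            if self.sharing_mode == "csm" and val.ndim not in (0, 1):
                raise InvalidParameterError(f"CSM requires scalar or 1-D {name}")
            object.__setattr__(self, name, val)
        if self.reset_mode == "soft" and not np.all(np.isfinite(self.v_th)):
            raise InvalidParameterError("soft reset requires a finite v_th")

    def validate_channels(self, channels: int):
        """CSM parameter arrays must have length equal to the channel count."""
        for name in ("alpha", "beta", "v_th", "v_reset", "r_gain"):
            val = getattr(self, name)
            if np.ndim(val) == 1 and len(val) != channels:
                raise InvalidParameterError(
                    f"CSM {name} has length {len(val)}, expected {channels} channels"
                )

    def expand(self, name: str, state_ndim: int):
        """Broadcastable view of a parameter against state [B, C, *spatial]."""
        val = getattr(self, name)
        if np.ndim(val) == 0:
            return val
        return np.reshape(val, (len(val),) + (1,) * (state_ndim - 2))


@dataclass
class NeuronState:
    """Per-neuron state carried across timesteps.

    ``v`` is the membrane potential with the layer's output shape
    [B, C, *spatial]; ``aux`` holds variant-specific state (synaptic
    filters, adaptive thresholds, refractory counters, ...).
    """

    v: Tensor
    aux: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, shape, v_init: float = 0.0) -> "NeuronState":
        return cls(v=Tensor(np.full(shape, float(v_init))))


@dataclass(frozen=True)
class ContinuousLIFParams:
    """Continuous-time LIF parameters: tau dV/dt = -(V - V_rest) + R*I."""

    tau: float
    v_rest: float = 0.0
    r_in: float = 1.0
    dt: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise InvalidParameterError("tau must be > 0")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        if self.dt > self.tau:
            raise InvalidParameterError("dt must not exceed tau (Euler validity)")


def continuous_to_discrete(p: ContinuousLIFParams, **overrides) -> NeuronParams:
    """Euler-discretise continuous LIF parameters.

    ``alpha = 1 - dt/tau``, ``beta = (dt/tau) * v_rest`` and ``r_gain``
    chosen so that ``alpha * r_gain = (dt/tau) * r_in``, which makes one
    step of :func:`neuron_step` reproduce the explicit Euler step of the
    membrane ODE term by term.  In the memoryless limit ``dt == tau``
    (``alpha == 0``) that relation has no finite solution; ``r_gain`` is
    then set to ``r_in`` and the neuron retains no input (see methods note).
    """
    k = p.dt / p.tau
    alpha = 1.0 - k
    beta = k * p.v_rest
    r_gain = k * p.r_in / alpha if alpha > 0 else p.r_in
    return NeuronParams(alpha=alpha, beta=beta, r_gain=r_gain, **overrides)


def _check_input(state: NeuronState, i_t) -> Tensor:
    i_t = Tensor.as_tensor(i_t)
    if i_t.shape != state.v.shape:
        raise ContractError(
            f"input current shape {i_t.shape} != membrane shape {state.v.shape}"
        )
    if np.isnan(i_t.data).any():
        warnings.warn("NaN in input current; propagating", RuntimeWarning)
    return i_t


def neuron_step(
    state: NeuronState, input_current, params: NeuronParams
) -> tuple[Tensor, NeuronState]:
    """Advance a LIF/LIAF layer by one timestep.

    Returns ``(output, new_state)``; the output is the binary spike map for
    spiking mode or ``f(V)`` of the post-leak potential for analog mode.
    """
    i_t = _check_input(state, input_current)
    nd = state.v.ndim
    alpha = params.expand("alpha", nd)
    beta = params.expand("beta", nd)
    v_th = params.expand("v_th", nd)
    v_reset = params.expand("v_reset", nd)
    r_gain = params.expand("r_gain", nd)

    if np.ndim(r_gain) == 0 and float(r_gain) == 1.0:
        v_m = state.v + i_t
    else:
        v_m = state.v + i_t * r_gain
    f = spike(v_m, v_th, params.surrogate.width)
    if params.reset_mode == "hard":
        r = f * v_reset + (1.0 - f) * v_m
    else:  # soft (residual membrane potential)
        r = f * (v_m - v_th) + (1.0 - f) * v_m
    v_new = alpha * r + beta
    if params.fire_mode == "spike":
        y = f
    else:
        y = ACTIVATIONS[params.activation](v_new)
    return y, NeuronState(v=v_new, aux=state.aux)


def surrogate_spike_grad(v_m, v_th, spec: Optional[SurrogateSpec] = None):
    """Surrogate derivative of the fire condition w.r.t. the potential.

    Rectangular window: ``1/width`` for ``|v_m - v_th| <= width/2``, zero
    outside; integrates to 1 over the potential axis.
    """
    spec = spec or SurrogateSpec()
    v_m = np.asarray(v_m, dtype=np.float64)
    v_th = np.asarray(v_th, dtype=np.float64)
    return (np.abs(v_m - v_th) <= spec.width / 2.0) / spec.width


def with_fire_mode(params: NeuronParams, fire_mode: str) -> NeuronParams:
    return replace(params, fire_mode=fire_mode)
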