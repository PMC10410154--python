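# stp — spatiotemporal processing with neural dynamics

`stp` builds, trains, profiles, and exports deep networks in which the
*spatial* computation is ordinary convolution / linear algebra and the
*temporal* computation comes from bio-inspired neural dynamics: discrete
leaky integrate-and-fire (LIF) neurons embedded inside the layer stack.
It is aimed at people studying lightweight alternatives to Conv3D/ConvLSTM
for sequence perception — event-camera (DVS) streams, video motion,
3-D image stacks, token sequences — and at computational-neuroscience
users who want configurable neuron models and synaptic plasticity inside
a trainable deep network.

Everything exchanges data as a dense **ST tensor** `[B, T, C, H, W]`
(batch, timesteps, channels, height, width; `[B, T, S]` for 1-D signals).

## The model

Each spatiotemporal (ST) block is *synapse → homeostasis → dynamics*:
a 2-D convolution or linear map, optional batch normalization, and a
LIF layer executing per timestep

```
V_m^t = V^{t-1} + r·I^t                 integrate
F^t   = [V_m^t ≥ V_th]                  fire (inclusive)
R^t   = F^t·V_reset + (1-F^t)·V_m^t     hard reset
      | F^t·(V_m^t - V_th) + (1-F^t)·V_m^t   soft reset (RMP)
V^t   = α·R^t + β                       leak
Y^t   = F^t  (LIF)   |   f(V^t)  (LIAF)
```

with multiplicative/additive decays `α, β`, shared per layer (ASM) or per
channel (CSM). The LIAF variant transmits an analog activation of the
potential instead of the binary spike. A **LIF+** registry factors the
step into five configurable stages (decay, spike accumulation, trigger,
inhibition, refractory) for neuron-model exploration.

Networks run in two equivalent iteration modes — the time loop inside
each block (IIM, natural for BPTT training) or outside the network (EIM,
matching timestep-driven neuromorphic hardware, with a running
accumulator in place of temporal aggregation) — and can be compiled to a
**state-aware computational graph**: a single-timestep dataflow graph
whose membrane potentials become load/save node pairs keyed by UUIDs,
with the neuron math lowered to `cmp_and_fire` / `reset_with_decay`
builtins. Graph execution is bitwise identical to direct execution.

Training is **surrogate-gradient BPTT** (exact Heaviside forward, a
rectangular unit-area window backward). Local learning implements
trace-based plasticity `t ← Θ·t + η·S`, `ΔW = t_in·S_out − S_in·t_out`
(Hebb / STDP / reward-modulated STDP with population-coded readout), and
a co-learning schedule alternates global BPTT phases with streamed local
phases. A closed-form complexity model counts multiplications, additions
and weights per layer kind (ConvLIF/ConvLIAF/Conv2D/Conv3D/ConvLSTM).

No external dataset is required: `stp.synthetic` generates labeled
moving-bar event streams whose classes differ only in motion direction,
so they are unsolvable from time-aggregated frames.

## Worked example

Train the shipped two-block ConvLIF classifier on the 3-class moving-bar
task (200 train / 60 validation samples, T=20, 20×20, two polarity
channels):

```
$ stp train -c examples/motion_lif.yaml
{"epoch": 14, "lr": 0.001, "loss_scale": 1.0, "train_loss": 0.0039,
 "train_acc": 1.0, "val_acc": 1.0}
```

The final line is the last epoch's metrics: the network reaches 100%
validation accuracy — the classes are spatially identical (a left-moving
bar visits exactly the pixels of a right-moving one), so this accuracy is
attributable to the membrane dynamics extracting motion direction.

Profile the same network:

```
$ stp profile -c examples/motion_lif.yaml
    kind  t  h  w  c  k   mul    add  weights
conv_lif 20 10 10  8  2 16000 320000      152
conv_lif 20  5  5 16  8  8000 592000     1168
{"mul": 24000, "add": 912000, "weights": 1320}
```

Spiking (ConvLIF) layers need only `R = T·H·W·C` multiplications — the
binary spikes turn the synaptic multiply-accumulate into pure addition —
which is where the lightweight-processing claim comes from.

Other commands: `stp run` (IIM/EIM inference), `stp simulate-data`,
`stp export-graph` / `stp run-graph`, `stp colearn` (global-local
co-learning). Library use mirrors the CLI; see `stp/__init__.py` for the
public surface and `docs/methods.md` for the science.

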