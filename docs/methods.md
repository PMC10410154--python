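# Methods

## Membrane model and its discretisation

The continuous membrane is the standard leaky integrator
`τ dV/dt = -(V - V_rest) + R·I(t)` with firing at `V_th` and reset to
`V_reset`. `continuous_to_discrete` applies one explicit Euler step of
size `dt` and regroups terms into the discrete parameters
`α = 1 - dt/τ`, `β = (dt/τ)·V_rest`, and an input gain `r` fixed by
`α·r = (dt/τ)·R` so that one call of `neuron_step` reproduces the Euler
step term by term. Validity requires `0 < dt ≤ τ` (so `α ∈ [0, 1)`).
In the memoryless corner `dt = τ` the relation above has no finite
solution for `r`; we return `r = R` there and note that the discrete
neuron then retains nothing between steps. In networks `r` defaults to 1
— an input resistance is indistinguishable from a rescaling of the
synaptic weights feeding the neuron, so it is folded into them.

The per-timestep procedure is integrate → fire → reset → leak → output,
i.e. the decay multiplies the *post-reset* potential. A historically
common alternative applies the decay jointly to `V^{t-1} + r·I`; the two
differ in where the leak acts relative to the reset, and we implement the
tensorised procedure above throughout (dynamics, training, and the
exported graph all share it, which is what makes the equivalence checks
bitwise).

Numerical conventions: the fire comparison is inclusive (`V_m ≥ V_th`
fires); the membrane initialises to 0 and is reset before the first
timestep of every sample; NaN/Inf input currents propagate unchanged but
emit a warning — they are never clamped. The LIAF activation `f` applies
to the post-leak potential `V^t` and defaults to the rectifier.

## Surrogate gradient

The forward spike is the exact step function; the backward pass uses a
rectangular window of width 1 (configurable) centred on the threshold,
height `1/width`, so it integrates to one over the potential axis. The
rectangle is unbiased and cheap; nothing in the package depends on the
window's shape beyond its support, and the width trades gradient sparsity
against bias in the usual way.

## LIF+ stage registry

The LIF variants are factored into five stages, each a small registry:

* **A — decay**: 0 fixed `(α, β)`; 1 learnable per-channel multiplicative
  decay (the decay becomes a trained parameter).
* **B — spike accumulation**: 0 direct current injection; 1 alpha-synapse
  low-pass `s ← k·s + I` (default `k = 0.5`); 2 dual-exponential
  (difference of a decay and a rise filter, defaults 0.8/0.3);
  3 instantaneous current pulse with a gain (no persistent synaptic
  state).
* **C — trigger**: 0 fixed threshold; 1 adaptive threshold
  `θ ← ρ·θ + c·F` added to `V_th` (defaults ρ=0.9, c=0.1); 2 stochastic
  threshold with Gaussian jitter (σ=0.1, seeded at state reset).
* **D — inhibition**: 0 off; 1 winner-take-all across the channel axis —
  among the neurons that crossed threshold at a location, only the one
  with the highest `V_m` fires (lowest index on ties).
* **E — refractory**: 0 off; 1 fixed period `p` (default 2): a counter is
  set to `p` on firing and decremented each step; a neuron may fire only
  at counter 0, so consecutive spikes are at least `p` steps apart.

These definitions are this package's documented reading of the stage
taxonomy; the all-zero configuration short-circuits to the plain LIF step
and is bitwise identical to it. Gating masks (D, E) and threshold noise
(C2) act as constants in the backward pass; the stage-B filters are part
of the differentiable recurrence, so those variants train with BPTT
unchanged. The graph exporter lowers only default dynamics — the
hardware builtins model plain LIF/LIAF — and refuses non-default LIF+
configurations.

## Blocks, homeostasis, and iteration modes

An ST block is synapse (conv2d with "same" padding and bias, or linear) →
optional batch normalization → dynamics. During training, normalization
statistics pool over batch *and* time (stable even at batch 1 streaming);
inference uses the running estimates, which is what lets step-wise
external iteration match sequence-wise internal iteration exactly. 1-D
signals reuse the fully connected path on `[B, T, S]`; an FC block
flattens spatial inputs, so it can directly follow a conv stack.

IIM wraps each block in its own reset + time loop and permits per-block
temporal transforms (subsample-by-k, sum-pool-by-k — the minimal useful
set). EIM runs one frame through all blocks per timestep and replaces
temporal aggregation with a running accumulator `Acc(i) = Acc(i-1) +
Input(i)`, `Acc(-1) = 0`, whose final value equals the sum over
timesteps exactly (the sum aggregation is itself computed by sequential
accumulation in timestep order for this reason). For any plan with a
shared T and no temporal transforms the two modes execute the same
floating-point operations in the same order and agree bitwise. State is
reset automatically at sample boundaries in batch mode; in streaming
mode resets are explicit, and reuse of stale state across a declared
sample-id change raises an error.

## Training

BPTT unrolls the internal-iteration forward pass; gradients flow through
the surrogate spike derivative and the membrane recurrence, and states
are rebuilt at each sample boundary so nothing leaks across samples.
Optimisers: SGD with momentum and Adam, weight decay added to the raw
gradient, cosine/step/none schedules. The classification loss is softmax
cross-entropy on the aggregated logits (the natural choice for the
classification heads; nothing else in the design depends on it).
Optional half-precision training casts parameters and inputs to float16
for the forward/backward pass, amplifies the loss by a configurable
factor (default 512), de-amplifies the gradients before the update on
the float64 master weights, and halves the factor (skipping the step)
whenever a non-finite gradient appears. It is off by default.

The engine underneath is a ~400-line reverse-mode tape over numpy arrays
(`stp._tensor`): elementwise ops with broadcasting, matmul, im2col
convolution, reductions, indexing, the spike op, and a fused
cross-entropy. The same numpy kernels implement the graph runtime, which
is why graph execution matches direct execution bitwise.

## Local plasticity and co-learning

Traces decay as `t ← Θ·t + η·S` on both sides of the synapse; the STDP
update is the outer-product form `ΔW[i,j] = t_in[i]·S_out[j] −
S_in[i]·t_out[j]`. Per timestep the order is: update traces with the
current spikes, compute ΔW, apply — making the simultaneous-spike case
(`ΔW = 0` at Θ=0, η=1) self-consistent. The Hebb rule uses the raw
coincidence `S_in·S_out` (the trace form degenerates to zero there).

The reward uses population coding: with N neurons per category the
category activity is the population mean and the reward is the one-hot
label minus that mean, constant across a category's neurons (our reading
of the per-neuron index in the reward; it vanishes exactly at the label
pattern). The printed STDP rule carries no reward term; reward
modulation is therefore applied multiplicatively per output neuron,
`ΔW[:, j] ← r_j·ΔW[:, j]`, the standard R-STDP form. Updates are
streamed: batch size one, weight step `w ← w + lr·Δw` at every timestep
(no averaging over time), with the reward recomputed each timestep from
the instantaneous output spikes. Defaults follow the co-learning recipe:
`lr = 0.001`, `Θ = 0.95`, `η = 1.0`, N = 7 per category, target array =
the last fully connected spiking layer.

Co-learning alternates global phases (plain BPTT, plasticity detached)
and local phases (all weights frozen except the target array).
Normalization layers cannot be plasticity targets.

## Data pipelines

* **Events → ST**: (x, y) is (column, row); windows are half-open
  `[k·t_s, (k+1)·t_s)`; polarity 1 (intensity increase) fills channel 0,
  polarity 0 channel 1; pixels hold event counts, optionally binarised.
  Spatial subsampling uses a centred crop to a divisible extent followed
  by integer-factor binning (e.g. 128 → crop 120 → bin 3 → 40); a
  non-integer resampling ratio is deliberately not supported.
  Out-of-bounds events are dropped and counted in the log.
* **Frames → differences**: adjacent-frame subtraction with a dead band:
  enhancement channel `d > thr`, weakening channel `d < −thr`.
* **Volumes**: values clamped to a gray window (default [−1200, 600]
  Hounsfield units) and mapped linearly to [0, 255]; slices become
  timesteps. Out-of-window values clamp rather than error.
* **Tokens**: right-padded with id 0 to a fixed length; overlong
  sequences keep their first `pad_len` tokens.
* **Background noise**: per channel of every frame, exactly
  `floor(ratio·W·H)` distinct pixels are forced to 1, deterministically
  per seed.

## Synthetic data

The generator emulates gesture-style event recordings: a 2-pixel bar
sweeps one pixel per timestep across a 20×20 field (defaults; T = 20)
with a random, wrap-around start offset; the class is the direction
(left/right/up/down). Opposite directions are exact time reversals of
each other and visit identical pixel sets, so any time-aggregated
statistic is class-blind — solving the task requires temporal modelling,
which is the property the benchmarks of interest share. Events are
leading-edge ON / trailing-edge OFF transitions of the bar mask;
training tensors are the binarised binned events `[N, T, 2, H, W]`.
What the generator does *not* emulate: sensor noise statistics,
timestamp jitter, object deformation, scene clutter, or class diversity
beyond direction. Passing tests on it demonstrate that the machinery
(dynamics, gradients, modes, plasticity) works, not that any particular
accuracy transfers to real recordings.

Reference problem sizes used by the test suite: 200 training / 60
validation samples, 3 classes (left, right, up), batch 20, Adam with
lr 1e-3 and weight decay 1e-4, 15–20 epochs — small enough to run on one
CPU core in about a minute while leaving a wide margin to the accuracy
property being checked.

## Complexity model

Closed forms per layer kind in terms of `R = T·H·W·C` output elements
and `Q = I·J·K` multiply-accumulates per element, including the
elementwise neuron dynamics and excluding normalization; weight counts
are synaptic weights plus biases. "Total operations" for ratio summaries
means MUL + ADD. The brute-force cross-check instantiates the actual
parameter arrays (the package's own conv blocks; explicit kernel/gate
arrays for Conv3D and ConvLSTM, the latter with four gates each holding
input kernel, recurrent kernel, and bias) and counts elements.

## Graph export

Only networks runnable in external iteration export (shared T, default
dynamics, not in training mode). Each membrane and the readout
accumulator become a load/save pair keyed by a fresh UUID with a
zero-fill constant initializer (shapes stored without the batch axis;
the runtime binds the batch size from the input frame). Serialization is
JSON with an explicit schema version; arrays are inlined as base64 with
dtype and shape. Deserialization re-validates the full structure —
unknown ops, dangling references, duplicated or unmatched state ids,
in-timestep cycles, and version mismatches all fail loudly.

## Known limitations

* No synaptic delays and no sparse event-driven execution — computation
  is dense tensor algebra throughout.
* The streaming (batch-1) path agrees with batched execution to
  floating-point rounding, not bitwise, because BLAS may reorder the
  single-row matmul reduction.
* Half-precision support is a loss-scaling mechanism, not a tuned
  mixed-precision recipe.
* The LIF+ registry is one documented reading of the five-stage
  taxonomy; stage definitions beyond it (and electrically coupled
  neuron populations) are out of scope.
* Video decoding is out of scope: frame sequences are consumed as image
  files or arrays.
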