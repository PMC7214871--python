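# Methods

## Network graphs and streaming rollouts

A network graph is a DAG of layer nodes — an initial 3×3 convolution (the
input node, where frames are injected), densely connected blocks, 3×3-conv +
2×2-average-pool transitions, a global-average-pool node and a fully-connected
readout. Every edge carries a delay `d_ANN` in rollout frames (1 throughout,
though the forward/backward passes and the simulator accept general integer
delays per edge).

In the DenseNet-style constructor, the block input connects to every layer of
its block and each layer to all later layers; the block's concatenation
(block input + all layer outputs) feeds the next transition or, after the
last block, the global-pool node, which feeds the classifier. Path lengths
are measured from the input node to the classifier, so

- `l_s = n_blocks + 1` (skip through every block, then pool → readout),
- `l_max = n_blocks · (n_layers + 1) + 1`,
- `τ = l_max − l_s + 1 = n_blocks · n_layers + 1 = D`, the depth.

The receptive field equaling the depth is a property of this construction:
each block contributes one frame of temporal spread per layer. The canonical
single-block illustration (initial conv + three densely connected layers
feeding an FC readout directly, no pooling stage) is provided separately as
`fig_example_graph()` with `l_s = 2`, `l_max = 4`, `τ = 3`.

Rollout indexing: frames are 1-based, input frame `i` feeds rollout frame
`i`, outputs appear at frames `l_s + 1 … K` with `K = N + l_s` — exactly `N`
outputs, the last connected to the last input via the shortest path. When
`N < τ`, inputs are spread over the `τ` input slots as slot `round(i·τ/N)`
and the rollout keeps its full `τ + l_s` frames; this even-spreading rule is
one admissible choice among several and is isolated in `rollout()`.

Dependency cones are computed from the exact set of realizable input→output
path lengths (a DP over the DAG), not just the interval `[l_s, l_max]`; for
densely connected graphs the two coincide.

## The rollout ANN and training

Every node is `a = ReLU(Linear(concat(predecessors)))` with the linear map a
3×3 "same" convolution, convolution followed by 2×2 average pooling
(transitions), or a dense layer; the classifier applies global average
pooling and a dense readout without ReLU, and softmax lives in the loss.
Restricting the architecture to ReLU + average pooling (no max pooling, no
batch norm) is what keeps rate-based conversion a per-layer linear rescaling.
Pooling is placed *inside* the transition node after its convolution, so each
node is a single linear map followed by ReLU — the exact form the IF-rate
mapping assumes.

Parameters are shared across rollout frames. Training is
backpropagation-through-time over the unrolled DAG, implemented directly in
numpy (im2col convolutions; gradients verified against central finite
differences to ~1e-10 in the test suite). The loss is
`L = Σ_k −a_k log(y_k[true])` with the per-output factors `a_k` normalized to
sum to one (schemes: uniform, linear/exponentially increasing or decreasing,
inverse, first-only, last-only; indices use the actual rollout-frame number).
Log arguments are clamped at 1e−12.

Optimizer: Adam (lr 1e−3, β = 0.9/0.999), batch 64, weight decay 1e−4 (L2 on
weights, not biases), activation decay 1e−6 (L2 on all hidden activations
summed over rollout frames, for sparsity and hence fewer spikes after
conversion), optional per-channel spatial dropout (default 0). The model
with the best validation accuracy after any epoch is kept; training stops
early once the last `perfect_tail` outputs hold validation accuracy 1.0 for
two consecutive epochs. All randomness flows from a single seed.

Nodes outside their warm-up cone (before any input can have reached them) are
skipped rather than emitting bias-driven activity; this matches the converted
SNN, where deep layers are silent until spikes arrive through the delays.

## Conversion

Per weighted hidden node, the scale `λ_l` is the p-th percentile (default
99.9, the robust choice from the conversion literature) of all its
activations over a calibration set (default: 512 training samples), pooled
across all rollout frames. Weights into node `l` are scaled by `λ_src/λ_l`
per incoming branch (concatenated inputs keep their own source scale — the
only consistent treatment of DenseNet concatenations), biases by `1/λ_l`.
The weightless global-pool node passes per-channel scales through; the
classifier absorbs incoming scales into its weights and is left unnormalized
(it never spikes; positive rescaling preserves the argmax, verified
exhaustively in tests). A node whose calibration activations are all zero
gets `λ = 1` with a warning. Rescaling is exact: rescaled activations equal
the originals divided by `λ` to machine precision.

Axonal delays: every connection gets `d = n_sf · d_ANN` simulation steps, so
spikes traverse the graph exactly as activations traverse the rollout.

## Simulation

Non-leaky IF neurons, threshold `V_th = 1`, subtractive reset, at most one
spike per neuron per step (saturating units are accepted — the percentile
rescale deliberately lets a few saturate to speed up propagation), membrane
lower bound `V_min = 0` (clamped after integration) so sustained inhibition
within one frame cannot silence a neuron for many following frames.
Membranes start at `V(0) = 0` and persist across frame boundaries. Input
frames enter the first layer as analog constant currents (deterministic, no
Poisson encoding); biases are constant currents injected every step. Each
step is two-phase — all synaptic drives are gathered from the delay lines
before any neuron updates — so within-step ordering cannot leak information.

The readout accumulates the output layer's weighted input per step and
predicts the argmax of the trailing `n_sf`-step window (the paper-level
interval `T_F` corresponds to one rollout frame = `n_sf` steps); ties break
to the lowest class index. Per-frame SNN accuracy averages the per-step
correctness over that frame's steps.

Bias currents pass through the same pre-threshold pathway as synaptic input
(whether biases should saturate separately is undefined in the source method;
injecting them as ordinary currents preserves the rate mapping).

## Operation accounting

ANN: multiply-adds per node update — `9·C_in·C_out·H·W` for 3×3 convolutions
(plus `4·C·H_out·W_out` accumulates for the pool inside transitions),
`C_in·C_out` for dense layers, `C·H·W` for pooling/global-pooling
accumulations. Cumulative ops at output `k` sum all node updates in frames
`1..k`, skipping nodes before their warm-up cone. The count is
architecture-only, identical for every sample.

SNN: each spike costs its source neuron's fan-out. Fan-out maps account for
zero padding (a corner pixel feeds 4 positions of a 3×3 consumer, an edge
pixel 6, an interior pixel 9, times the consumer's channels), dense consumers
cost their output count, the global pool one accumulator synapse per spike,
the classifier its class count. Analog input-current injections are not
spikes and are not counted; neither is the pooling internal to a transition
(its spikes are consumed by the convolution's synapses).

`ρ = AUC(SNN)/AUC(ANN)` on the per-step grid; the ANN curve is piecewise
constant, holding each output's accuracy over its rollout frame and chance
(`1/C`) before the first output. `ρ` can marginally exceed 1 because the SNN
curve moves within frames while the ANN curve is frozen between outputs.

## Synthetic data

**Moving rectangles** (defaults: 16×16 canvas, rectangle sides 3–8 px, shift
2 px, 6 input frames = 2 images × 3 repeats, balanced classes, ON channel
binary, OFF channel zero; sizes chosen so the `N_l = 1` model trains on one
CPU in minutes). The first image's position is drawn uniformly over the
placements that admit both shift directions and is therefore exactly
independent of the label — outputs whose receptive cone covers only the first
image are provably at chance. The second image's position marginal cannot
also be label-independent on a bounded canvas (no distribution with bounded
support is invariant under both `+s` and `−s` translation), so late single
frames leak some border information; the probe tests accordingly assert
chance on first-image frames and far-below-perfect accuracy for any single
frame. The generator emulates the frame-based toy task only; it has none of
the noise, jitter, or polarity statistics of real event-camera data, so
passing tests demonstrate the temporal-integration mechanism, not real-DVS
robustness.

**Random event streams**: homogeneous Poisson, expected count
`rate · duration · H · W` over both polarities, sorted integer-microsecond
timestamps.

**Fixture networks**: small dense ReLU chains with non-negative-biased
weights (positive mean, some negative entries) and small positive biases.
Predominantly active units are the regime rate conversion targets; with
zero-mean random weights, fluctuating positive/negative drive interacts with
the membrane lower bound to produce spurious spikes in units whose mean drive
is negative — a real, documented cost of membrane clamping, excluded from the
fidelity fixtures by construction, not by filtering results.

## Problem sizes

The end-to-end experiment trains on 2048 generated samples (256 validation,
256 test), growth 8, up to 40 epochs with early stopping at perfect
validation on the last three outputs; conversion calibrates on 512 training
samples; the `n_sf` sweep uses 128 samples at `n_sf ∈ {5, 15, 35}`. The full
pipeline runs in a few minutes on a single CPU.

## Known limitations

- Recurrent (cyclic) edges and multi-delay temporal convolutions are out of
  scope; delays are per-edge integers with the streaming constraint `d ≥ 1`.
- The event-camera benchmark datasets (N-MNIST, N-CARS, CIFAR10-DVS,
  DvsGesture) require external downloads and GPU-scale training; the loaders
  and preprocessing (cutting, binning, bilinear downscale, frame stacking,
  packed 40-bit binary adapter) are implemented and tested on generated
  fixtures, but no benchmark accuracy is reproduced or asserted.
- Percentile scales pooled over all rollout frames overestimate early-frame
  activity (activity grows as more paths contribute), inflating early-output
  approximation error; adaptive/homeostatic threshold rescaling is not
  implemented.
- Leaky/refractory neuron models, spike-timing codes, event-driven
  simulation, quantization and hardware-energy measurement are out of scope;
  energy-per-operation figures are not asserted anywhere.
- The real-time condition `f · n_sf ≤ T_F` is reported as a formula only.
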