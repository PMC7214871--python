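"""Time-stepped simulation of converted IF networks with axonal delays.

Neuron model: non-leaky integrate-and-fire without refractory period.  At
every simulation step a neuron adds its synaptic drive (delayed presynaptic
spikes through the rescaled weights, plus the bias as a constant current, plus
-- for the input layer only -- the analog frame value as current), spikes once
if the membrane potential reaches the threshold ``v_th``, resets by
subtracting ``v_th``, and is clamped at the lower bound ``v_min`` so a burst
of inhibition cannot silence it for long.  At most one spike per neuron per
step; a unit whose target rate exceeds one saturates.

Each input frame is presented for ``n_sf`` consecutive steps and every
connection delays spikes by ``n_sf`` steps, so activity reproduces the
streaming rollout frame by frame.  Membrane potentials persist across frame
boundaries: the state at the end of one frame initializes the next, which
speeds up convergence of the rate approximation for slowly varying input.
Membranes start at ``V(0) = 0``.

The output layer never spikes: per step it accumulates its weighted input,
and the prediction is the argmax of the trailing ``n_sf``-step window sum
(ties break to the lowest class index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .convert import SpikingNetwork

__all__ = [
    "IFState",
    "SimResult",
    "Simulator",
    "run",
    "snn_accuracy_curve",
]


@dataclass
class IFState:
    """Mutable simulation state for a batch of samples.

    ``v[nid]``: membrane potentials (B, C, H, W); ``lines[nid]``: circular
    spike buffer (d, B, C, H, W) holding the last ``d`` steps of node ``nid``'s
    output spikes; ``window``: ring of the readout layer's per-step weighted
    input over the trailing ``n_sf`` steps; ``t``: completed steps.
    """

    v: dict[int, np.ndarray]
    lines: dict[int, np.ndarray]
    window: np.ndarray
    t: int = 0


@dataclass
class SimResult:
    predictions: np.ndarray  # (B, T) argmax of the readout window after each step
    scores: np.ndarray  # (B, n_classes, T) window sums after each step
    spike_counts: np.ndarray  # (T, n_nodes) total spikes per step (batch summed)
    ops: np.ndarray | None = None  # (B, T) synaptic operations per step
    record: dict[int, np.ndarray] | None = None  # nid -> (T, B, C, H, W) spikes


class Simulator:
    """Step-by-step IF simulation of a :class:`SpikingNetwork`."""

    def __init__(self, snn: SpikingNetwork, batch_size: int, dtype=np.float32):
        self.snn = snn
        self.batch = batch_size
        self.dtype = np.dtype(dtype)
        model = snn.model
        self.out_id = model.graph.output_id
        self.in_id = model.graph.input_id
        self.order = model.graph.topological_order()
        self.spiking = [nid for nid in self.order if nid != self.out_id]
        v = {}
        lines = {}
        for nid in self.spiking:
            meta = model.meta[nid]
            shape = (batch_size, meta.out_channels, *meta.out_hw)
            v[nid] = np.zeros(shape, dtype=self.dtype)  # V(0) = 0
            d = max(
                (snn.delay(nid, t) for t in model.graph.successors(nid)), default=1
            )
            lines[nid] = np.zeros((d, *shape), dtype=self.dtype)
        window = np.zeros((snn.n_sf, batch_size, model.n_classes), dtype=self.dtype)
        self.state = IFState(v=v, lines=lines, window=window)

    def _delayed_input(self, nid: int) -> np.ndarray:
        """Concatenate predecessor spikes from ``t - d`` for each connection."""
        st, model = self.state, self.snn.model
        parts = []
        for p in model.graph.predecessors(nid):
            d = self.snn.delay(p, nid)
            t_src = st.t + 1 - d  # current step is t+1
            if t_src < 1:
                meta = model.meta[p]
                parts.append(
                    np.zeros((self.batch, meta.out_channels, *meta.out_hw), dtype=self.dtype)
                )
            else:
                parts.append(st.lines[p][(t_src - 1) % st.lines[p].shape[0]])
        return parts[0] if len(parts) == 1 else np.concatenate(parts, axis=1)

    def step(self, external: np.ndarray | None) -> dict[int, np.ndarray]:
        """Advance one simulation step; returns the spikes emitted per node.

        ``external`` is the analog input frame (B, C, H, W) injected as a
        constant current into the input layer (None for zero input).
        """
        st, snn, model = self.state, self.snn, self.snn.model
        drives: dict[int, np.ndarray] = {}
        # phase 1: gather all synaptic drives from the delayed buffers
        for nid in self.order:
            if nid == self.in_id:
                if external is None:
                    b = model.params[nid].get("b")
                    meta = model.meta[nid]
                    drive = np.zeros((self.batch, meta.out_channels, *meta.out_hw), dtype=self.dtype)
                    if b is not None:
                        drive += b.reshape(1, -1, *([1] * (drive.ndim - 2))).astype(self.dtype)
                else:
                    drive = model._node_linear(nid, np.asarray(external, dtype=model.dtype))
            else:
                drive = model._node_linear(nid, self._delayed_input(nid))
            drives[nid] = np.asarray(drive, dtype=self.dtype)
        # phase 2: integrate, fire, reset, clamp; advance buffers and readout
        spikes: dict[int, np.ndarray] = {}
        for nid in self.spiking:
            v = st.v[nid]
            v += drives[nid]
            if not np.all(np.isfinite(v)):
                bad = np.argwhere(~np.isfinite(v))[0]
                raise FloatingPointError(
                    f"non-finite membrane potential in node {nid} at unit {tuple(bad)}"
                )
            s = (v >= snn.v_th).astype(self.dtype)
            v -= s * self.dtype.type(snn.v_th)
            np.maximum(v, self.dtype.type(snn.v_min), out=v)
            spikes[nid] = s
            st.lines[nid][st.t % st.lines[nid].shape[0]] = s
        out = drives[self.out_id]
        if out.ndim == 4:
            out = out.reshape(self.batch, -1)
        st.window[st.t % snn.n_sf] = out
        st.t += 1
        return spikes

    def window_scores(self) -> np.ndarray:
        """Readout-window class scores: sum over the trailing min(t, n_sf) steps."""
        n = min(self.state.t, self.snn.n_sf)
        if n == 0:
            return np.zeros((self.batch, self.snn.model.n_classes), dtype=self.dtype)
        if n < self.snn.n_sf:
            idx = [(self.state.t - 1 - i) % self.snn.n_sf for i in range(n)]
            return self.state.window[idx].sum(axis=0)
        return self.state.window.sum(axis=0)


def run(
    snn: SpikingNetwork,
    frames: np.ndarray,
    fanout: dict[int, np.ndarray] | None = None,
    record: bool = False,
    n_rollout_frames: int | None = None,
) -> SimResult:
    """Simulate a batch of frame sequences for ``T = n_sf * K`` steps.

    ``frames``: (B, N, C, H, W), the same preprocessing as for ANN training
    (the input layer's rescaled weights absorb the input normalization).
    Frame ``k`` drives steps ``(k-1)*n_sf + 1 .. k*n_sf``; rollout frames
    beyond ``N`` (the shortest-path tail of the rollout, ``K = N + l_s``)
    receive no external input.  If ``fanout`` maps are given (see
    :func:`snnstream.efficiency.fanout_maps`), per-step synaptic-operation
    counts are accumulated.
    """
    frames = np.asarray(frames)
    bsz, n_in = frames.shape[:2]
    sched = snn.model.schedule(n_in)
    slot_to_input = {s: i for i, s in sched.input_slot.items()}
    K = n_rollout_frames if n_rollout_frames is not None else sched.K
    n_sf = snn.n_sf
    T = n_sf * K
    sim = Simulator(snn, bsz)
    preds = np.zeros((bsz, T), dtype=np.int64)
    scores = np.zeros((bsz, snn.model.n_classes, T), dtype=np.float32)
    counts = np.zeros((T, len(sim.spiking)), dtype=np.int64)
    ops = np.zeros((bsz, T), dtype=np.float64) if fanout is not None else None
    rec: dict[int, list] | None = {nid: [] for nid in sim.spiking} if record else None
    for t in range(T):
        k = t // n_sf + 1  # rollout frame being presented
        i = slot_to_input.get(k)
        external = frames[:, i - 1] if i is not None else None
        spikes = sim.step(external)
        w = sim.window_scores()
        scores[:, :, t] = w
        preds[:, t] = w.argmax(axis=1)
        for j, nid in enumerate(sim.spiking):
            counts[t, j] = int(spikes[nid].sum())
            if ops is not None and nid in fanout:
                ops[:, t] += np.tensordot(spikes[nid], fanout[nid], axes=3)
            if rec is not None:
                rec[nid].append(spikes[nid].astype(np.uint8))
    return SimResult(
        predictions=preds,
        scores=scores,
        spike_counts=counts,
        ops=ops,
        record={nid: np.stack(r) for nid, r in rec.items()} if rec is not None else None,
    )


def snn_accuracy_curve(
    snn: SpikingNetwork,
    frames: np.ndarray,
    labels: np.ndarray,
    batch_size: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-simulation-step and per-rollout-frame accuracy over a dataset.

    The per-frame accuracy averages the per-step correctness over the ``n_sf``
    steps of that frame (the final frame's value is the network's headline
    accuracy).
    """
    labels = np.asarray(labels)
    total = None
    for start in range(0, len(frames), batch_size):
        res = run(snn, frames[start : start + batch_size])
        correct = (res.predictions == labels[start : start + batch_size, None]).sum(axis=0)
        total = correct if total is None else total + correct
    per_step = total / len(frames)
    per_frame = per_step.reshape(-1, snn.n_sf).mean(axis=1)
    return per_step, per_frame
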