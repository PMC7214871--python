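"""Operation counting and the accuracy ratio for efficiency comparisons.

ANN cost is measured in multiply-add operations per rollout frame: a node's
count is its fan-in times its number of output units (for a 3x3 convolution
``9 * C_in * C_out * H_out * W_out``), plus accumulate ops for average and
global pooling.  The count is fixed by the architecture -- identical for
every sample.

SNN cost is measured in synaptic operations: every emitted spike costs its
source neuron's fan-out (the number of synapses it feeds), so cost scales
with actual spiking activity.  Analog current injections into the input layer
are not spikes and are not counted.

The accuracy ratio ``rho`` compares an SNN to its source ANN on the
simulation-step axis: rho = AUC(SNN accuracy) / AUC(ANN accuracy), using
rectangular integration on the per-step grid.  Sweeping ``n_sf`` and plotting
rho against total operations locates the accuracy/energy trade-off; rho
saturates once the rate approximation is good enough.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annmodel import RolloutModel, ann_accuracy_curve
from .convert import ScaleFactors, SpikingNetwork, build_snn, calibrate_percentiles
from .netgraph import RolloutSchedule
from .snnsim import run

__all__ = [
    "count_ann_ops",
    "ann_ops_per_frame",
    "cumulative_ann_ops",
    "fanout_maps",
    "count_snn_ops",
    "ann_step_curve",
    "accuracy_ratio",
    "sweep_nsf",
]


def count_ann_ops(model: RolloutModel) -> dict[int, int]:
    """Multiply-add (and pooling accumulate) operations per node per update."""
    ops: dict[int, int] = {}
    for nid, meta in model.meta.items():
        h_in, w_in = meta.in_hw
        if meta.impl == "conv":
            n = 9 * meta.in_channels * meta.out_channels * h_in * w_in
            if meta.pool == 2:
                n += 4 * meta.out_channels * meta.out_hw[0] * meta.out_hw[1]
        elif meta.impl == "dense":
            n = meta.in_channels * h_in * w_in * meta.out_channels
        elif meta.impl == "gap":
            n = meta.in_channels * h_in * w_in
        else:  # classifier: optional global pool, then dense readout
            n = 0
            if h_in * w_in > 1:
                n += meta.in_channels * h_in * w_in
            n += meta.in_channels * meta.out_channels
        ops[nid] = n
    return ops


def ann_ops_per_frame(model: RolloutModel, schedule: RolloutSchedule) -> np.ndarray:
    """Total ANN ops executed in each rollout frame 1..K (warm-up cone skipped)."""
    per_node = count_ann_ops(model)
    return np.array(
        [sum(per_node[nid] for nid in schedule.active_nodes(k)) for k in range(1, schedule.K + 1)],
        dtype=np.int64,
    )


def cumulative_ann_ops(model: RolloutModel, schedule: RolloutSchedule) -> np.ndarray:
    """Cumulative ANN ops up to and including each rollout frame."""
    return np.cumsum(ann_ops_per_frame(model, schedule))


def fanout_maps(snn: SpikingNetwork) -> dict[int, np.ndarray]:
    """Per-neuron synapse fan-out for every spiking node, as (C, H, W) maps.

    A 3x3 "same" convolution gives an interior source pixel 9 target positions
    per output channel, edge pixels 6 and corner pixels 4 (zero padding means
    those synapses do not exist).  A dense consumer contributes its full
    output count, a global-pool consumer one accumulator synapse, and the
    classifier its class count.
    """
    model = snn.model
    maps: dict[int, np.ndarray] = {}
    for nid, meta in model.meta.items():
        if meta.impl == "classifier":
            continue
        c, (h, w) = meta.out_channels, meta.out_hw
        fan = np.zeros((c, h, w), dtype=np.float64)
        for succ in model.graph.successors(nid):
            sm = model.meta[succ]
            if sm.impl == "conv":
                cover = np.zeros((h, w))
                ones = np.ones((h, w))
                for du in (-1, 0, 1):
                    for dv in (-1, 0, 1):
                        ys = slice(max(0, -du), h - max(0, du))
                        xs = slice(max(0, -dv), w - max(0, dv))
                        yt = slice(max(0, du), h - max(0, -du))
                        xt = slice(max(0, dv), w - max(0, -dv))
                        cover[ys, xs] += ones[yt, xt]
                fan += cover[None, :, :] * sm.out_channels
            elif sm.impl == "dense":
                fan += sm.out_channels
            elif sm.impl == "gap":
                fan += 1.0
            else:  # classifier (global pool + dense readout)
                fan += sm.out_channels
        maps[nid] = fan
    return maps


def count_snn_ops(snn: SpikingNetwork, record: dict[int, np.ndarray]) -> np.ndarray:
    """Cumulative synaptic operations per step from a full spike record.

    ``record[nid]``: (T, B, C, H, W) spike indicators as produced by
    :func:`snnstream.snnsim.run` with ``record=True``.  Every spike costs its
    source neuron's fan-out.  Returns (B, T) cumulative counts.
    """
    maps = fanout_maps(snn)
    unknown = set(record) - set(maps)
    if unknown:
        raise ValueError(f"spike record references unknown/non-spiking nodes {sorted(unknown)}")
    per_step = None
    for nid, spikes in record.items():
        contrib = np.tensordot(spikes.astype(np.float64), maps[nid], axes=3)  # (T, B)
        per_step = contrib if per_step is None else per_step + contrib
    if per_step is None:
        raise ValueError("empty spike record")
    return np.cumsum(per_step.T, axis=1)


def ann_step_curve(
    acc_by_frame: dict[int, float],
    schedule: RolloutSchedule,
    n_sf: int,
    n_classes: int,
) -> np.ndarray:
    """Expand per-output-frame ANN accuracies to the simulation-step axis.

    The curve is piecewise constant: during the ``n_sf`` steps of rollout
    frame ``k`` it holds the accuracy of the most recent output at or before
    ``k`` (chance ``1/n_classes`` before the first output).
    """
    chance = 1.0 / n_classes
    vals = []
    current = chance
    for k in range(1, schedule.K + 1):
        if k in acc_by_frame:
            current = acc_by_frame[k]
        vals.extend([current] * n_sf)
    return np.asarray(vals)


def accuracy_ratio(ann_curve: np.ndarray, snn_curve: np.ndarray) -> float:
    """rho = AUC(SNN) / AUC(ANN), both on the same per-step grid."""
    ann_curve = np.asarray(ann_curve, dtype=np.float64)
    snn_curve = np.asarray(snn_curve, dtype=np.float64)
    if ann_curve.shape != snn_curve.shape:
        raise ValueError("curves must share the simulation-step grid")
    denom = ann_curve.sum()
    if denom <= 0:
        raise ValueError("ANN curve has zero area under the curve")
    return float(snn_curve.sum() / denom)


def sweep_nsf(
    model: RolloutModel,
    frames: np.ndarray,
    labels: np.ndarray,
    nsf_list: list[int],
    percentile: float = 99.9,
    calib_frames: np.ndarray | None = None,
    scale: ScaleFactors | None = None,
    batch_size: int = 256,
) -> pd.DataFrame:
    """Convert and simulate at each ``n_sf``; tabulate rho and operation counts.

    Returns a DataFrame with columns (n_sf, rho, ann_mops, snn_mops), sorted
    by ``n_sf``; operation counts are totals for one sample (ANN: full
    rollout; SNN: mean total synaptic ops over the dataset), in millions.
    """
    labels = np.asarray(labels)
    if scale is None:
        scale = calibrate_percentiles(model, calib_frames if calib_frames is not None else frames, percentile)
    sched = model.schedule(frames.shape[1])
    ann_acc = ann_accuracy_curve(model, frames, labels, batch_size=batch_size)
    ann_total = float(cumulative_ann_ops(model, sched)[-1])
    maps = None
    rows = []
    for n_sf in sorted(nsf_list):
        snn = build_snn(model, scale, n_sf)
        if maps is None:
            maps = fanout_maps(snn)
        correct = None
        ops_total = 0.0
        n = 0
        for start in range(0, len(frames), batch_size):
            res = run(snn, frames[start : start + batch_size], fanout=maps)
            c = (res.predictions == labels[start : start + batch_size, None]).sum(axis=0)
            correct = c if correct is None else correct + c
            ops_total += float(res.ops.sum())
            n += res.predictions.shape[0]
        snn_curve = correct / n
        ann_curve = ann_step_curve(ann_acc, sched, n_sf, model.n_classes)
        rows.append(
            {
                "n_sf": n_sf,
                "rho": accuracy_ratio(ann_curve, snn_curve),
                "ann_mops": ann_total / 1e6,
                "snn_mops": ops_total / n / 1e6,
            }
        )
    return pd.DataFrame(rows)
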