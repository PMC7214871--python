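"""ANN-to-SNN conversion: percentile rescaling and delay assignment.

Rate-based conversion maps each ReLU unit with activation ``a`` onto a
non-leaky integrate-and-fire neuron whose firing rate approximates ``a``
spikes per simulation step.  Since a neuron cannot exceed one spike per step,
activations are first normalized: every weighted node ``l`` is assigned a
scale ``lambda_l`` -- the p-th percentile of its activations over a
calibration set, pooled across all rollout frames -- and its parameters are
rescaled so that the new activations are ``a / lambda_l``.  Using a high
percentile instead of the maximum lets a few neurons saturate but raises
overall activity, which speeds up information propagation.

Weights into node ``l`` are multiplied by ``lambda_source / lambda_l`` (for
concatenated inputs each branch uses its own source scale) and biases by
``1 / lambda_l``.  The weightless global-pool node passes its incoming
per-channel scales through unchanged; the readout layer absorbs the incoming
scales into its weights and is left unnormalized (it never spikes, and a
positive rescaling of class scores preserves the argmax).

Temporal structure: the ANN rollout gives every edge a delay of ``d_ann``
rollout frames; when each rollout frame is approximated by ``n_sf``
simulation steps, the corresponding axonal delay in the SNN must be
``d = n_sf * d_ann`` steps so information arrives exactly as during training.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from .annmodel import RolloutModel

__all__ = [
    "ScaleFactors",
    "SpikingNetwork",
    "calibrate_percentiles",
    "rescale",
    "build_snn",
]


@dataclass
class ScaleFactors:
    """Per-node activation scales ``lambda_l`` (weighted hidden nodes only)."""

    by_node: dict[int, float]
    percentile: float

    def __post_init__(self) -> None:
        for nid, lam in self.by_node.items():
            if not lam > 0:
                raise ValueError(f"scale for node {nid} must be positive, got {lam}")


def calibrate_percentiles(
    model: RolloutModel,
    frames: np.ndarray,
    percentile: float = 99.9,
    batch_size: int = 256,
) -> ScaleFactors:
    """Compute ``lambda_l`` for every weighted hidden node in one pass.

    ``frames``: calibration samples (B, N, C, H, W), typically a subset of the
    training set.  All activation values of a node are pooled over samples and
    over all rollout frames; the scale is their ``percentile``-th percentile.
    A node with all-zero activations gets scale 1 (with a warning).
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    if len(frames) == 0:
        raise ValueError("calibration set must be non-empty")
    hidden = [
        nid for nid, meta in model.meta.items() if meta.impl in ("conv", "dense")
    ]
    pooled: dict[int, list[np.ndarray]] = {nid: [] for nid in hidden}
    for start in range(0, len(frames), batch_size):
        _, acts, _ = model.forward(frames[start : start + batch_size], collect=True)
        for nid in hidden:
            for a in acts[nid].values():
                pooled[nid].append(np.asarray(a, dtype=np.float64).ravel())
    scales: dict[int, float] = {}
    for nid in hidden:
        vals = np.concatenate(pooled[nid]) if pooled[nid] else np.zeros(1)
        lam = float(np.percentile(vals, percentile))
        if lam <= 0:
            warnings.warn(f"node {nid}: all calibration activations are zero; scale set to 1")
            lam = 1.0
        scales[nid] = lam
    return ScaleFactors(scales, percentile)


def _incoming_scales(model: RolloutModel, out_scale: dict[int, np.ndarray], nid: int) -> np.ndarray:
    """Per-input-channel scale vector for node ``nid`` (concatenation order)."""
    if nid == model.graph.input_id:
        return np.ones(model.meta[nid].in_channels)
    return np.concatenate([out_scale[p] for p in model.graph.predecessors(nid)])


def rescale(model: RolloutModel, scale: ScaleFactors) -> RolloutModel:
    """Return a copy of ``model`` with percentile-rescaled parameters.

    The rescaled network's hidden activations equal the original's divided by
    the node scale (per incoming branch for the weightless global pool), and
    its class-score argmax matches the original on every input.
    """
    new = copy.copy(model)
    new.params = model.copy_params()
    out_scale: dict[int, np.ndarray] = {}
    for nid in model.graph.topological_order():
        meta = model.meta[nid]
        inc = _incoming_scales(model, out_scale, nid)
        if meta.impl == "gap":
            out_scale[nid] = inc  # passthrough: channels keep their branch scale
            continue
        lam = scale.by_node.get(nid, 1.0) if meta.impl != "classifier" else 1.0
        w = new.params[nid]["W"]
        if meta.impl == "conv":
            w *= (inc / lam).astype(model.dtype)[None, :, None, None]
        else:
            if meta.impl == "classifier":
                per_in = inc
            else:
                per_in = np.repeat(inc, w.shape[1] // inc.size)  # flattened spatial
            w *= (per_in / lam).astype(model.dtype)[None, :]
        new.params[nid]["b"] *= model.dtype.type(1.0 / lam)
        out_scale[nid] = np.full(meta.out_channels, lam, dtype=np.float64)
    return new


@dataclass
class SpikingNetwork:
    """Converted IF network: rescaled parameters plus per-connection delays.

    The topology mirrors the network graph; every connection's delay is
    ``n_sf * d_ann`` simulation steps.  IF neurons have threshold ``v_th`` (1)
    with subtractive reset and a lower membrane bound ``v_min`` (0); the
    output layer is a non-spiking accumulator read out over a trailing window
    of ``n_sf`` steps.
    """

    model: RolloutModel  # rescaled parameters; defines topology and linear maps
    scale: ScaleFactors
    n_sf: int
    v_th: float = 1.0
    v_min: float = 0.0
    delays: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def graph(self):
        return self.model.graph

    def delay(self, source: int, target: int) -> int:
        return self.delays[(source, target)]


def build_snn(model: RolloutModel, scale: ScaleFactors, n_sf: int) -> SpikingNetwork:
    """Convert a trained rollout model into a spiking network.

    ``n_sf`` is the number of simulation steps per rollout frame; it controls
    the rate-approximation fidelity (and the energy cost) and fixes every
    axonal delay to ``n_sf * d_ann`` steps.
    """
    if n_sf < 1:
        raise ValueError("n_sf must be >= 1")
    rescaled = rescale(model, scale)
    for p in rescaled.params.values():
        for arr in p.values():
            if not np.all(np.isfinite(arr)):
                raise ValueError("rescaled parameters contain non-finite values")
    delays = {(s, t): n_sf * d for s, t, d in model.graph.edges}
    return SpikingNetwork(model=rescaled, scale=scale, n_sf=int(n_sf), delays=delays)


def save_snn(snn: SpikingNetwork, source_model: RolloutModel, path) -> None:
    """Persist the conversion: source parameters, scales and n_sf (HDF5)."""
    import h5py

    from .annmodel import save_model

    save_model(source_model, path)
    with h5py.File(path, "a") as f:
        f.attrs["n_sf"] = snn.n_sf
        f.attrs["percentile"] = snn.scale.percentile
        grp = f.create_group("scale")
        for nid, lam in snn.scale.by_node.items():
            grp.attrs[str(nid)] = lam


def load_snn(path) -> SpikingNetwork:
    import h5py

    from .annmodel import load_model

    model = load_model(path)
    with h5py.File(path, "r") as f:
        scale = ScaleFactors(
            {int(k): float(v) for k, v in f["scale"].attrs.items()},
            float(f.attrs["percentile"]),
        )
        n_sf = int(f.attrs["n_sf"])
    return build_snn(model, scale, n_sf)
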