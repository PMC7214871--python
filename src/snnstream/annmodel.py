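"""Weight-shared streaming-rollout ANN: forward pass, BPTT training, losses.

The rollout unfolds a :class:`~snnstream.netgraph.NetworkGraph` over ``K``
rollout frames.  One parameter set exists per graph node and is shared across
all frames; a node's activation at frame ``k`` is computed exclusively from
its predecessors' activations at frame ``k - d`` (here ``d = 1`` everywhere),
so all layers can update in parallel.  Every node is the canonical form
``a = ReLU(Linear(concat(predecessors)))`` where the linear map is a 3x3
convolution, a 3x3 convolution followed by 2x2 average pooling (transitions),
or a dense layer; the terminal classifier applies global average pooling and a
dense readout without ReLU.  Keeping every node in this form (ReLU activations,
average pooling only) is what makes the later rate-based conversion to
integrate-and-fire neurons exact up to sampling error.

Training minimizes a weighted sum of categorical cross-entropies over all
output frames, ``L = sum_k -a_k * log(y_k[true])``, with the ``a_k`` trading
off early against late accuracy.  Gradients are computed by backpropagation
through time over the unrolled DAG with manual numpy backward passes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .netgraph import NetworkGraph, RolloutSchedule, rollout

__all__ = [
    "RolloutModel",
    "LossWeights",
    "TrainConfig",
    "make_loss_weights",
    "rollout_loss",
    "forward_rollout",
    "train",
    "ann_accuracy_curve",
]

LOG_EPS = 1e-12  # clamp for log() in the cross entropy
LOSS_SCHEMES = (
    "uniform",
    "linear-increasing",
    "exp-increasing",
    "first-only",
    "inverse",
    "exp-decreasing",
    "last-only",
)


# ---------------------------------------------------------------------------
# Primitive layers (stride-1 "same" 3x3 conv, 2x2 average pool, dense)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, C, 3, 3, H, W) sliding 3x3 patches, zero padding 1."""
    b, c, h, w = x.shape
    xp = np.zeros((b, c, h + 2, w + 2), dtype=x.dtype)
    xp[:, :, 1:-1, 1:-1] = x
    cols = np.empty((b, c, 3, 3, h, w), dtype=x.dtype)
    for u in range(3):
        for v in range(3):
            cols[:, :, u, v] = xp[:, :, u : u + h, v : v + w]
    return cols


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 convolution, stride 1, zero padding 1."""
    cols = _im2col(x)
    y = np.tensordot(cols, w, axes=([1, 2, 3], [1, 2, 3]))  # (B, H, W, Co)
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + b[None, :, None, None]


def conv2d_backward(
    x: np.ndarray, w: np.ndarray, gy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dW, db, dx) of :func:`conv2d` given upstream gradient ``gy``."""
    bsz, c, h, wd = x.shape
    cols = _im2col(x)
    dw = np.tensordot(gy, cols, axes=([0, 2, 3], [0, 4, 5]))  # (Co, C, 3, 3)
    db = gy.sum(axis=(0, 2, 3))
    dcols = np.tensordot(gy, w, axes=([1], [0]))  # (B, H, W, C, 3, 3)
    dxp = np.zeros((bsz, c, h + 2, wd + 2), dtype=x.dtype)
    for u in range(3):
        for v in range(3):
            dxp[:, :, u : u + h, v : v + wd] += np.ascontiguousarray(
                dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
            )
    return dw, db, dxp[:, :, 1:-1, 1:-1]


def avgpool2(x: np.ndarray) -> np.ndarray:
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool2_backward(gy: np.ndarray) -> np.ndarray:
    b, c, h, w = gy.shape
    return np.repeat(np.repeat(gy, 2, axis=2), 2, axis=3) * np.asarray(0.25, dtype=gy.dtype)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class _NodeMeta:
    impl: str  # "conv", "dense" or "classifier"
    in_channels: int
    out_channels: int
    in_hw: tuple[int, int]
    out_hw: tuple[int, int]
    pool: int = 1


class RolloutModel:
    """A network graph with one shared parameter set per node.

    Parameters live in ``params[node_id] = {"W": ..., "b": ...}``; the same
    arrays are used at every rollout frame (weight sharing across time).
    """

    def __init__(
        self,
        graph: NetworkGraph,
        input_spec: tuple[int, int, int],
        n_classes: int,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.graph = graph
        self.input_spec = tuple(input_spec)
        self.n_classes = int(n_classes)
        self.dtype = np.dtype(dtype)
        self.meta: dict[int, _NodeMeta] = {}
        self.params: dict[int, dict[str, np.ndarray]] = {}
        self._schedules: dict[int, RolloutSchedule] = {}
        self._delay = {(s, t): d for s, t, d in graph.edges}
        self._build(seed)

    # -- construction ------------------------------------------------------

    def _build(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        c_in0, h0, w0 = self.input_spec
        for nid in self.graph.topological_order():
            node = self.graph.node(nid)
            preds = self.graph.predecessors(nid)
            if node.kind == "input":
                in_c, in_hw = c_in0, (h0, w0)
            else:
                metas = [self.meta[p] for p in preds]
                hws = {m.out_hw for m in metas}
                if len(hws) != 1:
                    raise ValueError(
                        f"node {nid}: predecessor spatial sizes differ: {sorted(hws)}"
                    )
                in_hw = hws.pop()
                in_c = sum(m.out_channels for m in metas)
            dense = bool(node.params.get("dense"))
            if node.kind == "global-pool":
                # weightless per-channel global average; one unit per channel
                self.meta[nid] = _NodeMeta("gap", in_c, in_c, in_hw, (1, 1))
                self.params[nid] = {}
                continue
            if node.kind == "fully-connected":
                n_out = int(node.params["classes"])
                self.meta[nid] = _NodeMeta("classifier", in_c, n_out, in_hw, (1, 1))
                w = rng.normal(0.0, np.sqrt(1.0 / in_c), size=(n_out, in_c))
            elif dense:
                n_out = int(node.params["channels"])
                self.meta[nid] = _NodeMeta("dense", in_c, n_out, in_hw, (1, 1))
                w = rng.normal(0.0, np.sqrt(2.0 / in_c), size=(n_out, in_c))
            else:
                n_out = int(node.params["channels"])
                pool = int(node.params.get("pool", 1))
                out_hw = (in_hw[0] // pool, in_hw[1] // pool)
                if pool not in (1, 2):
                    raise ValueError(f"node {nid}: unsupported pool factor {pool}")
                if pool == 2 and (in_hw[0] % 2 or in_hw[1] % 2):
                    raise ValueError(f"node {nid}: cannot 2x2-pool odd size {in_hw}")
                self.meta[nid] = _NodeMeta("conv", in_c, n_out, in_hw, out_hw, pool)
                fan_in = 9 * in_c
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(n_out, in_c, 3, 3))
            self.params[nid] = {
                "W": w.astype(self.dtype),
                "b": np.zeros(n_out, dtype=self.dtype),
            }

    def schedule(self, n_frames: int) -> RolloutSchedule:
        if n_frames not in self._schedules:
            self._schedules[n_frames] = rollout(self.graph, n_frames)
        return self._schedules[n_frames]

    def copy_params(self) -> dict:
        return copy.deepcopy(self.params)

    def set_params(self, params: dict) -> None:
        self.params = copy.deepcopy(params)

    # -- forward -----------------------------------------------------------

    def _node_linear(self, nid: int, x: np.ndarray) -> np.ndarray:
        """Apply node ``nid``'s linear map (pre-ReLU) to its concatenated input."""
        meta = self.meta[nid]
        if meta.impl == "gap":
            return x.mean(axis=(2, 3))[:, :, None, None]
        w, b = self.params[nid]["W"], self.params[nid]["b"]
        if meta.impl == "conv":
            y = conv2d(x, w, b)
            if meta.pool == 2:
                y = avgpool2(y)
            return y
        if meta.impl == "classifier":
            flat = x.mean(axis=(2, 3))  # global average pool per channel
            return flat @ w.T + b
        flat = x.reshape(x.shape[0], -1)
        return (flat @ w.T + b).reshape(x.shape[0], meta.out_channels, 1, 1)

    def _node_input(
        self, nid: int, k: int, acts: dict[int, dict[int, np.ndarray]], batch: int
    ) -> np.ndarray:
        """Concatenate predecessor activations from frame ``k - d`` (zeros if silent)."""
        parts = []
        for p in self.graph.predecessors(nid):
            a = acts[p].get(k - self._delay[(p, nid)])
            if a is None:
                pm = self.meta[p]
                a = np.zeros((batch, pm.out_channels, *pm.out_hw), dtype=self.dtype)
            parts.append(a)
        return parts[0] if len(parts) == 1 else np.concatenate(parts, axis=1)

    def forward(
        self,
        frames: np.ndarray,
        collect: bool = False,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Run the streaming rollout on a batch of frame sequences.

        ``frames``: (B, N, C, H, W).  Returns ``(logits, acts, masks)`` where
        ``logits[k]`` are the classifier pre-softmax scores at output frame
        ``k`` and ``acts[nid][k]`` the hidden activations (only retained when
        ``collect`` is true, except for the trailing frame needed next).
        """
        frames = np.asarray(frames, dtype=self.dtype)
        if frames.ndim != 5:
            raise ValueError("frames must be (batch, N, C, H, W)")
        bsz, n_in = frames.shape[:2]
        if frames.shape[2:] != tuple(self.input_spec):
            raise ValueError(
                f"input frames {frames.shape[2:]} do not match input spec "
                f"{self.input_spec} of node {self.graph.input_id}"
            )
        sched = self.schedule(n_in)
        order = self.graph.topological_order()
        out_id = self.graph.output_id
        in_id = self.graph.input_id
        slot_to_input = {s: i for i, s in sched.input_slot.items()}
        acts: dict[int, dict[int, np.ndarray]] = {nid: {} for nid in order}
        masks: dict[int, dict[int, np.ndarray]] = {nid: {} for nid in order}
        logits: dict[int, np.ndarray] = {}
        out_frames = set(sched.output_frames)
        for k in range(1, sched.K + 1):
            for nid in order:
                if sched.node_earliest[nid] > k:
                    continue
                if nid == in_id:
                    i = slot_to_input.get(k)
                    if i is None:
                        continue
                    x = frames[:, i - 1]
                else:
                    if all(
                        acts[p].get(k - self._delay[(p, nid)]) is None
                        for p in self.graph.predecessors(nid)
                    ):
                        continue
                    x = self._node_input(nid, k, acts, bsz)
                if nid == out_id:
                    if k in out_frames:
                        logits[k] = self._node_linear(nid, x)
                    continue
                a = np.maximum(self._node_linear(nid, x), 0.0)
                if dropout > 0.0:
                    if rng is None:
                        raise ValueError("dropout requires an rng")
                    keep = rng.random((bsz, a.shape[1])) >= dropout
                    m = keep.astype(self.dtype) / self.dtype.type(1.0 - dropout)
                    if a.ndim == 4:
                        m = m[:, :, None, None]
                    a = a * m
                    masks[nid][k] = m
                acts[nid][k] = a
            if not collect:  # free activations older than the largest delay
                d_max = max(self._delay.values(), default=1)
                for nid in order:
                    acts[nid].pop(k - d_max, None)
        return logits, acts, masks


def forward_rollout(model: RolloutModel, frames: np.ndarray) -> dict[int, np.ndarray]:
    """Per-output-frame class probabilities (softmax of classifier scores)."""
    logits, _, _ = model.forward(np.asarray(frames))
    return {k: _softmax(z) for k, z in logits.items()}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Loss weighting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossWeights:
    """Per-output-frame loss factors ``a_k``, normalized to sum to one."""

    scheme: str
    a: dict[int, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.a.values()):
            raise ValueError("loss weights must be non-negative")
        s = sum(self.a.values())
        if not np.isclose(s, 1.0):
            raise ValueError(f"loss weights must sum to 1, got {s}")


def make_loss_weights(scheme: str, output_frames: list[int]) -> LossWeights:
    """Build the ``a_k`` factors for one of the named weighting schemes.

    Schemes use the actual rollout-frame index ``k`` (``uniform``: 1,
    ``linear-increasing``: k+1, ``exp-increasing``: exp(k), ``inverse``:
    1/(k+1), ``exp-decreasing``: exp(-k)); ``first-only``/``last-only`` put
    all weight on the first/last output frame.  Weights are normalized to
    sum to one to keep the effective learning rate scheme-independent.
    """
    if scheme not in LOSS_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {LOSS_SCHEMES}")
    ks = np.asarray(sorted(output_frames), dtype=np.float64)
    if ks.size == 0:
        raise ValueError("no output frames")
    if scheme == "uniform":
        w = np.ones_like(ks)
    elif scheme == "linear-increasing":
        w = ks + 1.0
    elif scheme == "exp-increasing":
        w = np.exp(ks - ks.max())
    elif scheme == "inverse":
        w = 1.0 / (ks + 1.0)
    elif scheme == "exp-decreasing":
        w = np.exp(-(ks - ks.min()))
    elif scheme == "first-only":
        w = np.zeros_like(ks)
        w[0] = 1.0
    else:  # last-only
        w = np.zeros_like(ks)
        w[-1] = 1.0
    w = w / w.sum()
    return LossWeights(scheme, {int(k): float(v) for k, v in zip(ks, w)})


def rollout_loss(
    outputs: dict[int, np.ndarray], labels: np.ndarray, weights: LossWeights
) -> float:
    """Weighted multi-output cross entropy ``sum_k -a_k log(y_k[true])``.

    ``outputs[k]`` are probability vectors; the target class is the same at
    every output frame.  Probabilities are clamped at ``1e-12`` before the log.
    Averaged over the batch.
    """
    labels = np.asarray(labels)
    total = 0.0
    for k, a_k in weights.a.items():
        if a_k == 0.0:
            continue
        p = np.clip(outputs[k][np.arange(len(labels)), labels], LOG_EPS, None)
        total += -a_k * float(np.mean(np.log(p)))
    return total


# ---------------------------------------------------------------------------
# Training (BPTT with Adam)
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 64
    lr: float = 1e-3
    weight_decay: float = 1e-4
    act_decay: float = 1e-6  # L2 penalty on hidden activations (sparsity)
    dropout: float = 0.0  # spatial dropout rate, training only
    loss_scheme: str = "uniform"
    seed: int = 0
    # stop early once the last `perfect_tail` outputs hold validation
    # accuracy 1.0 for `patience_at_perfect` consecutive epochs
    patience_at_perfect: int = 2
    perfect_tail: int = 1


def _loss_and_grads(
    model: RolloutModel,
    frames: np.ndarray,
    labels: np.ndarray,
    weights: LossWeights,
    cfg: TrainConfig,
    rng: np.random.Generator,
):
    """One forward/backward pass; returns (loss, grads) with grads summed over
    rollout frames (shared weights) and averaged over the batch."""
    bsz = frames.shape[0]
    sched = model.schedule(frames.shape[1])
    logits, acts, masks = model.forward(frames, collect=True, dropout=cfg.dropout, rng=rng)
    order = model.graph.topological_order()
    out_id, in_id = model.graph.output_id, model.graph.input_id
    dtype = model.dtype

    probs = {k: _softmax(z.astype(np.float64)) for k, z in logits.items()}
    loss = rollout_loss(probs, labels, weights)
    # regularization terms (reported in the loss, gradients added below)
    if cfg.act_decay:
        loss += cfg.act_decay * sum(
            float(np.sum(a.astype(np.float64) ** 2)) for d in acts.values() for a in d.values()
        ) / bsz
    if cfg.weight_decay:
        loss += 0.5 * cfg.weight_decay * sum(
            float(np.sum(p["W"].astype(np.float64) ** 2))
            for p in model.params.values()
            if "W" in p
        )

    grads = {
        nid: {key: np.zeros_like(v) for key, v in p.items()}
        for nid, p in model.params.items()
    }
    gacts: dict[int, dict[int, np.ndarray]] = {nid: {} for nid in order}
    onehot = np.zeros((bsz, model.n_classes), dtype=np.float64)
    onehot[np.arange(bsz), labels] = 1.0

    def backprop_linear(nid: int, k: int, gy: np.ndarray) -> None:
        """Backward through node nid's linear map at frame k; scatter to preds."""
        meta = model.meta[nid]
        if nid == in_id:  # reads the external frame; no upstream grads
            i = {s: j for j, s in sched.input_slot.items()}[k]
            x = np.asarray(frames[:, i - 1], dtype=dtype)
        else:
            x = model._node_input(nid, k, acts, bsz)
        w = model.params[nid].get("W")
        if meta.impl == "gap":
            h, wd = meta.in_hw
            dx = np.broadcast_to(
                gy.reshape(bsz, meta.in_channels, 1, 1) / (h * wd),
                (bsz, meta.in_channels, h, wd),
            ).astype(dtype)
            dw = db = None
        elif meta.impl == "conv":
            if meta.pool == 2:
                gy = avgpool2_backward(gy)
            dw, db, dx = conv2d_backward(x, w, gy)
            if nid == in_id:
                dx = None
        else:
            if meta.impl == "classifier":
                flat = x.mean(axis=(2, 3))
            else:
                gy = gy.reshape(bsz, -1)
                flat = x.reshape(bsz, -1)
            dw = gy.T @ flat
            db = gy.sum(axis=0)
            dflat = gy @ w
            if meta.impl == "classifier":
                h, wd = meta.in_hw
                dx = np.broadcast_to(
                    dflat[:, :, None, None] / (h * wd), (bsz, meta.in_channels, h, wd)
                ).astype(dtype)
            else:
                dx = dflat.reshape(bsz, meta.in_channels, *meta.in_hw)
        if dw is not None:
            grads[nid]["W"] += dw.astype(dtype)
            grads[nid]["b"] += db.astype(dtype)
        if dx is None:
            return
        c0 = 0
        for p in model.graph.predecessors(nid):
            pm = model.meta[p]
            c1 = c0 + pm.out_channels
            kd = k - model._delay[(p, nid)]
            if acts[p].get(kd) is not None:
                part = dx[:, c0:c1]
                prev = gacts[p].get(kd)
                gacts[p][kd] = part if prev is None else prev + part
            c0 = c1

    for k in range(sched.K, 0, -1):
        if k in logits:
            gz = ((probs[k] - onehot) * (weights.a.get(k, 0.0) / bsz)).astype(dtype)
            backprop_linear(out_id, k, gz)
        for nid in order:
            if nid == out_id:
                continue
            a = acts[nid].get(k)
            g = gacts[nid].pop(k, None)
            if a is None:
                continue
            if cfg.act_decay:
                reg = (2.0 * cfg.act_decay / bsz) * a
                g = reg if g is None else g + reg
            if g is None:
                continue
            m = masks[nid].get(k)
            if m is not None:
                g = g * m
            g = g * (a > 0)
            backprop_linear(nid, k, g)

    if cfg.weight_decay:
        for nid in grads:
            if "W" in grads[nid]:
                grads[nid]["W"] += dtype.type(cfg.weight_decay) * model.params[nid]["W"]
    return loss, grads


def train(
    model: RolloutModel,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
):
    """Train in place with Adam; returns ``(model, history)``.

    The model with the best validation accuracy (final output frame) seen
    after any epoch is restored at the end.  Deterministic given
    ``config.seed``.  Raises on a non-finite loss.
    """
    cfg = config or TrainConfig()
    x_train, y_train = train_data
    x_val, y_val = val_data
    rng = np.random.default_rng(cfg.seed)
    sched = model.schedule(x_train.shape[1])
    weights = make_loss_weights(cfg.loss_scheme, sched.output_frames)

    m_state = {nid: {k: np.zeros_like(v) for k, v in p.items()} for nid, p in model.params.items()}
    v_state = {nid: {k: np.zeros_like(v) for k, v in p.items()} for nid, p in model.params.items()}
    step = 0
    history: list[dict] = []
    best_acc, best_params = -1.0, model.copy_params()
    perfect_streak = 0

    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(x_train))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            loss, grads = _loss_and_grads(model, x_train[idx], y_train[idx], weights, cfg, rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss {loss} at epoch {epoch}, "
                    f"batch {n_batches}"
                )
            epoch_loss += loss
            n_batches += 1
            step += 1
            b1c = 1.0 - 0.9**step
            b2c = 1.0 - 0.999**step
            for nid, g in grads.items():
                for key in g:
                    m_state[nid][key] = 0.9 * m_state[nid][key] + 0.1 * g[key]
                    v_state[nid][key] = 0.999 * v_state[nid][key] + 0.001 * g[key] ** 2
                    upd = (m_state[nid][key] / b1c) / (np.sqrt(v_state[nid][key] / b2c) + 1e-8)
                    model.params[nid][key] -= model.dtype.type(cfg.lr) * upd
        val_curve = ann_accuracy_curve(model, x_val, y_val)
        tail = sorted(val_curve)[-cfg.perfect_tail :]
        val_acc = float(np.mean([val_curve[k] for k in tail]))
        history.append(
            {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1), "val_acc": val_acc}
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_params = model.copy_params()
        perfect_streak = perfect_streak + 1 if val_acc >= 1.0 else 0
        if perfect_streak >= cfg.patience_at_perfect:
            break
    model.set_params(best_params)
    return model, history


def save_model(model: RolloutModel, path) -> None:
    """Checkpoint: graph, input spec, and all shared parameters (HDF5)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["graph"] = model.graph.to_json()
        f.attrs["input_spec"] = model.input_spec
        f.attrs["n_classes"] = model.n_classes
        f.attrs["dtype"] = model.dtype.name
        for nid, p in model.params.items():
            grp = f.create_group(f"node/{nid}")
            for key, v in p.items():
                grp.create_dataset(key, data=v)


def load_model(path) -> RolloutModel:
    import h5py

    from .netgraph import NetworkGraph

    with h5py.File(path, "r") as f:
        graph = NetworkGraph.from_json(f.attrs["graph"])
        model = RolloutModel(
            graph,
            tuple(int(v) for v in f.attrs["input_spec"]),
            int(f.attrs["n_classes"]),
            dtype=np.dtype(f.attrs["dtype"]),
        )
        for nid in model.params:
            grp = f[f"node/{nid}"]
            for key in model.params[nid]:
                model.params[nid][key] = grp[key][...].astype(model.dtype)
    return model


def ann_accuracy_curve(
    model: RolloutModel, frames: np.ndarray, labels: np.ndarray, batch_size: int = 256
) -> dict[int, float]:
    """Accuracy of ``argmax(y_k)`` per output frame, averaged over the dataset."""
    labels = np.asarray(labels)
    correct: dict[int, int] = {}
    for start in range(0, len(frames), batch_size):
        xb = frames[start : start + batch_size]
        yb = labels[start : start + batch_size]
        logits, _, _ = model.forward(xb)
        for k, z in logits.items():
            correct[k] = correct.get(k, 0) + int(np.sum(z.argmax(axis=1) == yb))
    return {k: c / len(frames) for k, c in sorted(correct.items())}
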