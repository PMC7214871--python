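"""Synthetic inputs: moving rectangles, random event streams, fixture networks.

The moving-rectangles task is a minimal temporal-integration problem: a sample
is a pair of binary images with one rectangle each, the second image being the
first shifted horizontally by a fixed offset whose sign is the class (left /
right).  Each image is repeated over half the input frames, so the direction
can only be read out by comparing information from both halves of the
sequence -- a single image carries (almost) no class information.

The first image's position is drawn uniformly over the placements that admit
both shift directions, so it is exactly independent of the label; the shifted
image's position marginal necessarily differs slightly between classes near
the canvas borders (no bounded-support distribution is invariant under both
+shift and -shift), which caps single-frame accuracy well below 100% without
reaching chance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annmodel import RolloutModel
from .events import EventStream
from .netgraph import chain_graph

__all__ = [
    "RectanglesDataset",
    "gen_rectangles",
    "gen_random_events",
    "gen_fixture_network",
]

LEFT, RIGHT = 0, 1


@dataclass
class RectanglesDataset:
    """Frames (n, n_frames, 2, H, W) float32 and labels (n,) in {0: left, 1: right}."""

    frames: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)

    def split(self, *sizes: int) -> list["RectanglesDataset"]:
        """Split into consecutive disjoint subsets of the given sizes."""
        if sum(sizes) > len(self):
            raise ValueError(f"cannot split {len(self)} samples into {sizes}")
        out, start = [], 0
        for s in sizes:
            out.append(RectanglesDataset(self.frames[start : start + s], self.labels[start : start + s]))
            start += s
        return out


def gen_rectangles(
    n_samples: int,
    height: int = 16,
    width: int = 16,
    shift: int = 2,
    size_range: tuple[int, int] = (3, 8),
    n_frames: int = 6,
    seed: int = 0,
) -> RectanglesDataset:
    """Balanced moving-rectangles dataset, deterministic given ``seed``.

    Each sample holds ``n_frames`` input frames: the first half repeats image
    A, the second half image B = A shifted by ``+shift`` (label "right") or
    ``-shift`` (label "left").  The rectangle is drawn on the ON channel with
    value 1; the OFF channel is zero.  Both rectangles lie fully inside the
    canvas.
    """
    if shift < 1:
        raise ValueError("shift must be >= 1")
    if n_frames % 2:
        raise ValueError("n_frames must be even (half per image)")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad size range {size_range}")
    if hi + 2 * shift > width or hi > height:
        raise ValueError(
            f"geometry impossible: rectangle up to {hi} px with shift {shift} "
            f"does not fit a {height}x{width} canvas"
        )
    rng = np.random.default_rng(seed)
    half = n_frames // 2
    labels = np.zeros(n_samples, dtype=np.int64)
    labels[: n_samples // 2] = RIGHT  # exactly balanced (odd n: one extra left)
    rng.shuffle(labels)
    frames = np.zeros((n_samples, n_frames, 2, height, width), dtype=np.float32)
    for i in range(n_samples):
        w = int(rng.integers(lo, hi + 1))
        h = int(rng.integers(lo, hi + 1))
        y0 = int(rng.integers(0, height - h + 1))
        # uniform over placements legal for BOTH directions: independent of label
        x_a = int(rng.integers(shift, width - w - shift + 1))
        x_b = x_a + (shift if labels[i] == RIGHT else -shift)
        frames[i, :half, 0, y0 : y0 + h, x_a : x_a + w] = 1.0
        frames[i, half:, 0, y0 : y0 + h, x_b : x_b + w] = 1.0
    return RectanglesDataset(frames, labels)


def gen_random_events(
    height: int,
    width: int,
    rate: float,
    duration_ms: float,
    seed: int = 0,
) -> EventStream:
    """Homogeneous-Poisson ON/OFF events: expected total count is
    ``rate * duration_ms * height * width`` (both polarities combined,
    ``rate`` in events per pixel per millisecond)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(rate * duration_ms * height * width)) if rate > 0 else 0
    t = np.sort(rng.integers(0, max(int(duration_ms * 1000), 1), size=n)).astype(np.int64)
    return EventStream(
        x=rng.integers(0, width, size=n).astype(np.int64),
        y=rng.integers(0, height, size=n).astype(np.int64),
        t=t,
        p=rng.integers(0, 2, size=n).astype(np.int64),
        height=height,
        width=width,
    )


def gen_fixture_network(
    depth: int,
    width: int,
    seed: int = 0,
    n_classes: int = 2,
    bias_scale: float = 0.05,
    dtype=np.float64,
) -> RolloutModel:
    """Small random dense ReLU chain for conversion/simulation equivalence tests.

    ``depth`` hidden layers of ``width`` units each (desk scale: depth <= 5,
    width <= 32).  Weights are non-negative-biased (positive mean with some
    negative entries) and biases small and non-negative, keeping most units
    active -- the regime rate-based conversion targets; with predominantly
    negative drive the membrane lower bound would otherwise let fluctuating
    inputs elicit spurious spikes.  Deterministic given ``seed``.
    """
    if depth > 5 or width > 32:
        raise ValueError("fixture networks are desk scale: depth <= 5, width <= 32")
    graph = chain_graph(depth + 1, width=width, n_classes=n_classes)
    model = RolloutModel(graph, (width, 1, 1), n_classes, seed=seed, dtype=dtype)
    rng = np.random.default_rng(seed + 1)
    for nid, p in model.params.items():
        if "W" in p and model.meta[nid].impl == "dense":
            w = (1.0 + 0.6 * rng.standard_normal(p["W"].shape)) / p["W"].shape[1]
            p["W"][:] = w.astype(model.dtype)
        if "b" in p:
            p["b"][:] = (bias_scale * rng.random(p["b"].shape)).astype(model.dtype)
    return model
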