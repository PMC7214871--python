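"""Event streams from dynamic vision sensors and their conversion to frames.

A DVS pixel emits an ON or OFF *event* when the log-intensity at that pixel
rises or falls past a threshold; a recording is a sequence of
``(x, y, t, polarity)`` records (address-event representation).  Networks in
this package consume *frame sequences*: the recording is cut into ``N`` equal
intervals of length ``T_F`` and events are accumulated per pixel into separate
ON and OFF channels, either as raw counts or as average rates (counts / T_F).

Native containers are a plain CSV (columns ``x,y,t,p``) and an NPZ archive;
``aer40`` is an adapter for the 40-bit packed binary dialect used by several
event-camera datasets (byte layout: x, y, then polarity bit plus a 23-bit
microsecond timestamp, big-endian).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _ski_resize

__all__ = [
    "EventStream",
    "FrameSequence",
    "read_events",
    "write_events",
    "events_to_frames",
    "cut_events",
    "downscale",
    "stack_frames",
    "load_frames",
    "save_frames",
]

ON, OFF = 1, 0  # polarity codes; channel order in frames is (ON, OFF)


@dataclass
class EventStream:
    """Sorted DVS events on an H x W sensor.

    ``x``: column (0-based), ``y``: row, ``t``: timestamp in microseconds,
    ``p``: polarity (1 = ON, 0 = OFF).
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    p: np.ndarray
    height: int
    width: int

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.p) == n):
            raise ValueError("event field arrays must have equal length")
        if n and np.any(np.diff(self.t) < 0):
            order = np.argsort(self.t, kind="stable")
            self.x, self.y, self.t, self.p = (a[order] for a in (self.x, self.y, self.t, self.p))
        if n:
            if self.x.min() < 0 or self.x.max() >= self.width:
                raise ValueError("event x coordinate outside sensor")
            if self.y.min() < 0 or self.y.max() >= self.height:
                raise ValueError("event y coordinate outside sensor")
            if not np.isin(self.p, (0, 1)).all():
                raise ValueError("polarity must be 0 (OFF) or 1 (ON)")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Time of the final event in microseconds (0 for an empty stream)."""
        return float(self.t[-1]) if len(self) else 0.0


@dataclass
class FrameSequence:
    """``N x C x H x W`` non-negative frame stack with frame interval ``t_f`` (ms).

    For raw two-polarity frames ``C == 2`` with channel order (ON, OFF); after
    :func:`stack_frames` the channel axis is ``(frame-within-stack, polarity)``
    flattened, i.e. channel ``2*j + c`` holds polarity ``c`` of the ``j``-th
    stacked source frame.
    """

    frames: np.ndarray
    t_f: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4:
            raise ValueError("frames must be N x C x H x W")
        if np.any(self.frames < 0):
            raise ValueError("frame values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.frames.shape


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DIALECTS = ("csv", "npz", "aer40")


def read_events(path: str | Path, dialect: str = "csv", height: int | None = None, width: int | None = None) -> EventStream:
    """Load an event stream; events are sorted by timestamp on load.

    CSV and NPZ containers store the sensor size; for ``aer40`` the sensor
    ``height``/``width`` must be supplied.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "csv":
        with open(path) as fh:
            header = fh.readline().strip()
            if header.split(",")[:4] != ["x", "y", "t", "p"]:
                raise ValueError(f"{path}:1: expected header 'x,y,t,p', got {header!r}")
            hline = fh.readline().strip()
            if not hline.startswith("#"):
                raise ValueError(f"{path}:2: expected '# height width' comment line")
            try:
                h, w = (int(v) for v in hline[1:].split())
            except ValueError as exc:
                raise ValueError(f"{path}:2: malformed sensor-size line {hline!r}") from exc
            rows = []
            for lineno, line in enumerate(fh, start=3):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(",")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: malformed record {line!r}")
                try:
                    rows.append([int(v) for v in parts])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed record {line!r}") from exc
        arr = np.asarray(rows, dtype=np.int64).reshape(-1, 4)
        return EventStream(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], height=h, width=w)
    if dialect == "npz":
        with np.load(path) as z:
            return EventStream(
                z["x"].astype(np.int64), z["y"].astype(np.int64),
                z["t"].astype(np.int64), z["p"].astype(np.int64),
                height=int(z["height"]), width=int(z["width"]),
            )
    # aer40: 5 bytes per event
    if height is None or width is None:
        raise ValueError("aer40 dialect needs explicit sensor height and width")
    raw = np.fromfile(path, dtype=np.uint8)
    if raw.size % 5:
        raise ValueError(f"{path}: offset {5 * (raw.size // 5)}: truncated 40-bit record")
    raw = raw.reshape(-1, 5).astype(np.int64)
    x = raw[:, 0]
    y = raw[:, 1]
    p = (raw[:, 2] >> 7) & 1
    t = ((raw[:, 2] & 0x7F) << 16) | (raw[:, 3] << 8) | raw[:, 4]
    return EventStream(x, y, t, p, height=height, width=width)


def write_events(stream: EventStream, path: str | Path, dialect: str = "csv") -> None:
    path = Path(path)
    if dialect == "csv":
        with open(path, "w") as fh:
            fh.write("x,y,t,p\n")
            fh.write(f"# {stream.height} {stream.width}\n")
            for x, y, t, p in zip(stream.x, stream.y, stream.t, stream.p):
                fh.write(f"{int(x)},{int(y)},{int(t)},{int(p)}\n")
    elif dialect == "npz":
        np.savez_compressed(
            path, x=stream.x, y=stream.y, t=stream.t, p=stream.p,
            height=stream.height, width=stream.width,
        )
    elif dialect == "aer40":
        t = np.asarray(stream.t, dtype=np.int64)
        if t.size and t.max() >= 1 << 23:
            raise ValueError("aer40 timestamps limited to 23 bits of microseconds")
        out = np.empty((len(stream), 5), dtype=np.uint8)
        out[:, 0] = stream.x
        out[:, 1] = stream.y
        out[:, 2] = (np.asarray(stream.p, dtype=np.uint8) << 7) | ((t >> 16) & 0x7F).astype(np.uint8)
        out[:, 3] = ((t >> 8) & 0xFF).astype(np.uint8)
        out[:, 4] = (t & 0xFF).astype(np.uint8)
        out.tofile(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


# ---------------------------------------------------------------------------
# Binning and preprocessing
# ---------------------------------------------------------------------------


def cut_events(stream: EventStream, duration_us: float) -> EventStream:
    """Explicitly drop all events after ``duration_us`` microseconds."""
    keep = stream.t <= duration_us
    return EventStream(
        stream.x[keep], stream.y[keep], stream.t[keep], stream.p[keep],
        height=stream.height, width=stream.width,
    )


def events_to_frames(stream: EventStream, n_frames: int, mode: str = "average") -> FrameSequence:
    """Bin a stream into ``n_frames`` intervals of ``T_F = duration / N`` each.

    Intervals are half-open ``[k*T_F, (k+1)*T_F)`` with the last interval
    closed so the final event is kept.  ``mode="sum"`` yields per-pixel event
    counts, ``mode="average"`` the average event rate (counts / T_F, with T_F
    in milliseconds).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if mode not in ("sum", "average"):
        raise ValueError(f"unknown mode {mode!r}")
    h, w = stream.height, stream.width
    frames = np.zeros((n_frames, 2, h, w), dtype=np.float64)
    if len(stream) == 0:
        return FrameSequence(frames, t_f=0.0)
    duration = stream.duration
    t_f_us = duration / n_frames if duration > 0 else 1.0
    idx = np.minimum((stream.t / t_f_us).astype(np.int64), n_frames - 1)
    chan = np.where(stream.p == ON, 0, 1)
    np.add.at(frames, (idx, chan, stream.y, stream.x), 1.0)
    t_f_ms = t_f_us / 1000.0
    if mode == "average" and t_f_ms > 0:
        frames /= t_f_ms
    return FrameSequence(frames, t_f=t_f_ms)


def downscale(frames: FrameSequence, out_hw: tuple[int, int]) -> FrameSequence:
    """Bilinear per-channel, per-frame spatial resampling."""
    oh, ow = out_hw
    if oh < 1 or ow < 1:
        raise ValueError("target size must be >= 1 in both dimensions")
    n, c, h, w = frames.shape
    if oh > h or ow > w:
        warnings.warn(f"upscaling {h}x{w} -> {oh}x{ow}", stacklevel=2)
    flat = frames.frames.reshape(n * c, h, w)
    out = np.empty((n * c, oh, ow), dtype=np.float64)
    for i in range(n * c):
        out[i] = _ski_resize(flat[i], (oh, ow), order=1, anti_aliasing=False, preserve_range=True)
    out = np.clip(out, 0.0, None)
    return FrameSequence(out.reshape(n, c, oh, ow), t_f=frames.t_f)


def stack_frames(frames: FrameSequence, stack: int) -> FrameSequence:
    """Group ``stack`` consecutive frames into one multi-channel input.

    Output channel ``2*j + c`` is polarity channel ``c`` of the ``j``-th frame
    in the stack.  A trailing remainder not filling a whole stack is dropped
    (logged via warning).  The frame interval grows to ``stack * t_f``.
    """
    if stack < 1:
        raise ValueError("stack size must be >= 1")
    n, c, h, w = frames.shape
    n_out = n // stack
    if n_out * stack != n:
        warnings.warn(f"dropping {n - n_out * stack} trailing frames not filling a stack", stacklevel=2)
    data = frames.frames[: n_out * stack].reshape(n_out, stack * c, h, w)
    return FrameSequence(data, t_f=frames.t_f * stack)


# ---------------------------------------------------------------------------
# Frame container I/O (HDF5)
# ---------------------------------------------------------------------------


def save_frames(frames: FrameSequence, path: str | Path, labels: np.ndarray | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=frames.frames)
        f.attrs["t_f"] = frames.t_f
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels))


def load_frames(path: str | Path) -> tuple[FrameSequence, np.ndarray | None]:
    import h5py

    with h5py.File(path, "r") as f:
        frames = FrameSequence(f["frames"][...], t_f=float(f.attrs["t_f"]))
        labels = f["labels"][...] if "labels" in f else None
    return frames, labels
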