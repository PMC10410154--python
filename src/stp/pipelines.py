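"""Modality conversion to ST tensors.

Every supported input modality is converted to the dense spatiotemporal
tensor [B, T, C, H, W] (or [B, T, S] for 1-D signals):

* event streams (x, y, t, polarity) — binned into per-window, per-polarity
  event-count frames (optionally binarised),
* grayscale frame sequences — adjacent-frame differencing into
  enhancement/weakening channels,
* 3-D volumes — HU gray normalization, slices as timesteps,
* token sequences — right-padded integer arrays.

Coordinate convention: an event's (x, y) is (column, row); tensors are
indexed [T, C, row, col].  Time windows are half-open [k*t_s, (k+1)*t_s).
Channel 0 carries polarity 1 (intensity increase / enhancement), channel 1
polarity 0 (decrease / weakening).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError

logger = logging.getLogger(__name__)

__all__ = [
    "EventStream",
    "NoiseSpec",
    "events_to_st",
    "frames_to_diff",
    "volume_to_st",
    "tokens_to_st",
    "add_background_noise",
    "load_frame_dir",
]


def load_frame_dir(path, pattern: str = "*.png") -> np.ndarray:
    """Read an image directory as a grayscale frame sequence [T, H, W].

    Files are taken in sorted name order; RGB images are converted to
    grayscale by channel averaging.  Video decoding is out of scope —
    frames are consumed as image files for codec independence.
    """
    import imageio.v3 as iio

    files = sorted(Path(path).glob(pattern))
    if not files:
        raise ContractError(f"no frames matching {pattern!r} in {path}")
    frames = []
    for f in files:
        img = np.asarray(iio.imread(f), dtype=np.float64)
        if img.ndim == 3:
            img = img.mean(axis=2)
        frames.append(img)
    if len({f.shape for f in frames}) != 1:
        raise ContractError("frames have unequal shapes")
    return np.stack(frames)


@dataclass
class EventStream:
    """A plain table of events plus the sensor extents.

    ``x`` is the column index (< w_s), ``y`` the row index (< h_s), ``t``
    the timestamp, ``ps`` the polarity (1 = intensity increase).
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    ps: np.ndarray
    h_s: int
    w_s: int

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=np.float64)
        self.ps = np.asarray(self.ps, dtype=np.int64)
        n = len(self.x)
        if not (len(self.y) == len(self.t) == len(self.ps) == n):
            raise ContractError("event columns must have equal length")
        if not np.isin(self.ps, (0, 1)).all():
            raise ContractError("polarity must be 0 or 1")
        order = np.argsort(self.t, kind="stable")
        for name in ("x", "y", "t", "ps"):
            setattr(self, name, getattr(self, name)[order])

    def __len__(self):
        return len(self.x)

    @classmethod
    def from_csv(cls, path, h_s: int, w_s: int) -> "EventStream":
        df = pd.read_csv(path)
        return cls(df["x"].values, df["y"].values, df["t"].values,
                   df["ps"].values, h_s=h_s, w_s=w_s)

    def to_csv(self, path):
        pd.DataFrame({"x": self.x, "y": self.y, "t": self.t,
                      "ps": self.ps}).to_csv(path, index=False)


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise injection: per channel of every frame, a random
    subset of n = floor(noise_ratio * W * H) pixels is forced to 1."""

    noise_ratio: float
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.noise_ratio <= 1.0:
            raise ContractError("noise_ratio must be in [0, 1]")


def events_to_st(
    ev: EventStream,
    window: float,
    t_steps: int,
    out_hw: tuple[int, int] | None = None,
    binary: bool = False,
) -> np.ndarray:
    """Bin an event stream into an ST tensor [1, T, 2, H, W].

    Each time window [k*window, (k+1)*window) becomes one frame; each pixel
    of the polarity channel holds the event count in that window (or 1 if
    ``binary`` and the count is positive).  If ``out_hw`` is smaller than
    the sensor, coordinates are reduced by an integer binning factor after a
    centred crop to a divisible extent.  Out-of-bounds events are rejected
    and counted in the log.
    """
    if window <= 0:
        raise ContractError("window must be > 0")
    if t_steps < 1:
        raise ContractError("t_steps must be >= 1")
    x, y, t, ps = ev.x, ev.y, ev.t, ev.ps
    inb = (x >= 0) & (x < ev.w_s) & (y >= 0) & (y < ev.h_s)
    if not inb.all():
        logger.warning("rejected %d events outside sensor extents",
                       int((~inb).sum()))
        x, y, t, ps = x[inb], y[inb], t[inb], ps[inb]

    h, w = (ev.h_s, ev.w_s) if out_hw is None else out_hw
    if (h, w) != (ev.h_s, ev.w_s):
        fy, fx = ev.h_s // h, ev.w_s // w
        if fy < 1 or fx < 1:
            raise ContractError("out_hw larger than sensor extents")
        cy, cx = h * fy, w * fx  # centred crop to a binnable extent
        oy, ox = (ev.h_s - cy) // 2, (ev.w_s - cx) // 2
        keep = (y >= oy) & (y < oy + cy) & (x >= ox) & (x < ox + cx)
        x, y, t, ps = x[keep], y[keep], t[keep], ps[keep]
        y = (y - oy) // fy
        x = (x - ox) // fx

    out = np.zeros((1, t_steps, 2, h, w))
    k = np.floor(t / window).astype(np.int64)
    keep = (k >= 0) & (k < t_steps)
    # channel 0 <- polarity 1 (ON), channel 1 <- polarity 0 (OFF)
    ch = 1 - ps[keep]
    np.add.at(out, (0, k[keep], ch, y[keep], x[keep]), 1.0)
    if binary:
        out = (out > 0).astype(np.float64)
    return out


def frames_to_diff(frames, threshold: float) -> np.ndarray:
    """Adjacent-frame differencing of a grayscale sequence.

    Returns [1, T-1, 2, H, W]: channel 0 (enhancement) marks pixels whose
    value rose by more than ``threshold``, channel 1 (weakening) pixels that
    fell by more than ``threshold``; changes within the band are background.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ContractError("frames_to_diff needs >= 2 equally shaped frames")
    d = np.diff(frames, axis=0)
    out = np.stack([(d > threshold), (d < -threshold)], axis=1)
    return out[None].astype(np.float64)


def volume_to_st(volume, hu_range: tuple[float, float] = (-1200.0, 600.0)) -> np.ndarray:
    """Gray-normalise a slice stack: clamp to ``hu_range`` and map linearly
    to [0, 255]; slices become timesteps -> [1, D, 1, H, W]."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.size == 0:
        raise ContractError("empty volume")
    if volume.ndim != 3:
        raise ContractError("volume must be a [D, H, W] slice stack")
    lo, hi = hu_range
    gray = (np.clip(volume, lo, hi) - lo) * (255.0 / (hi - lo))
    return gray[None, :, None]


def tokens_to_st(tokens, vocab_size: int, pad_len: int = 500) -> np.ndarray:
    """Right-pad (or tail-truncate) an integer token sequence to [1, pad_len].

    The pad id is 0; ids must be < vocab_size.
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    if tokens.size and (tokens.min() < 0 or tokens.max() >= vocab_size):
        raise ContractError("token id outside [0, vocab_size)")
    out = np.zeros((1, pad_len), dtype=np.int64)
    n = min(len(tokens), pad_len)
    out[0, :n] = tokens[:n]
    return out


def add_background_noise(x: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Force n = floor(noise_ratio*W*H) random distinct pixels per channel of
    every frame to 1.  Deterministic for a given seed; the input is copied."""
    x = np.asarray(x)
    if x.ndim != 5:
        raise ContractError("expected an ST tensor [B, T, C, H, W]")
    b, t, c, h, w = x.shape
    n = int(np.floor(spec.noise_ratio * w * h))
    out = x.copy()
    if n == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    flat = out.reshape(b * t * c, h * w)
    for row in flat:
        row[rng.choice(h * w, size=n, replace=False)] = 1.0
    return out
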