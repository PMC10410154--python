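"""Synthetic moving-pattern data with direction-coded classes.

The generator emulates gesture-style event-camera recordings: a bright bar
sweeps across the field of view, and the class is the motion direction
(left / right / up / down).  Opposite directions visit exactly the same set
of pixels, so the classes are indistinguishable from any time-aggregated
frame statistic — recovering the label requires temporal modelling, as in
gesture benchmarks whose actions come in symmetric pairs.

Samples can be emitted as event streams (two polarities: leading-edge ON
events, trailing-edge OFF events), as grayscale frame sequences, or
directly as ST tensors (the binned event representation).  Everything is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ContractError
from .pipelines import EventStream, NoiseSpec, add_background_noise, events_to_st

__all__ = ["MotionDataset", "MOTION_CLASSES", "motion_frames",
           "gen_synthetic_motion"]

MOTION_CLASSES = ("left", "right", "up", "down")
_BAR_WIDTH = 2


@dataclass
class MotionDataset:
    """Labeled synthetic dataset; ``x`` is [N, T, C, H, W] when tensor- or
    frame-emitted, ``events`` the per-sample streams when event-emitted."""

    y: np.ndarray
    classes: tuple
    x: Optional[np.ndarray] = None
    events: Optional[list] = None
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.y)


def motion_frames(cls: str, start: int, t_steps: int, hw: tuple[int, int]) -> np.ndarray:
    """Binary frames [T, H, W] of a bar moving one pixel per step.

    The bar spans the full perpendicular extent, is ``2`` pixels thick, and
    wraps around.  ``start`` is its leading position at t = 0.  By
    construction ``motion_frames("left", s)[::-1]`` equals
    ``motion_frames("right", (s - (T-1)) % W)``, and likewise for up/down.
    """
    if cls not in MOTION_CLASSES:
        raise ContractError(f"unknown motion class {cls!r}; known: {MOTION_CLASSES}")
    h, w = hw
    if h < _BAR_WIDTH + 1 or w < _BAR_WIDTH + 1:
        raise ContractError("field of view too small for the moving bar")
    frames = np.zeros((t_steps, h, w))
    horiz = cls in ("left", "right")
    extent = w if horiz else h
    sign = 1 if cls in ("right", "down") else -1
    for t in range(t_steps):
        pos = (start + sign * t) % extent
        cols = [(pos + d) % extent for d in range(_BAR_WIDTH)]
        if horiz:
            frames[t][:, cols] = 1.0
        else:
            frames[t][cols, :] = 1.0
    return frames


def _frames_to_events(frames: np.ndarray, window: float) -> EventStream:
    """DVS-style events from a binary frame sequence: ON where a pixel turns
    on, OFF where it turns off; the first frame appears against darkness."""
    t_steps, h, w = frames.shape
    prev = np.zeros((h, w))
    xs, ys, ts, pss = [], [], [], []
    for t in range(t_steps):
        d = frames[t] - prev
        for ps, mask in ((1, d > 0), (0, d < 0)):
            ry, rx = np.nonzero(mask)
            xs.append(rx)
            ys.append(ry)
            ts.append(np.full(len(rx), (t + 0.5) * window))
            pss.append(np.full(len(rx), ps))
        prev = frames[t]
    return EventStream(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(ts),
        np.concatenate(pss), h_s=h, w_s=w,
    )


def gen_synthetic_motion(
    classes=("left", "right", "up"),
    t_steps: int = 20,
    hw: tuple[int, int] = (20, 20),
    n_samples: int = 200,
    seed: int = 0,
    emit: str = "st",
    noise_ratio: float = 0.0,
) -> MotionDataset:
    """Generate a labeled moving-bar dataset.

    ``emit``: "st" for binned-event ST tensors [N, T, 2, H, W] (the default
    training representation), "events" for raw per-sample
    :class:`~stp.pipelines.EventStream` tables, "frames" for grayscale
    sequences [N, T, 1, H, W].  Labels are balanced across classes and
    shuffled; ``noise_ratio`` adds background noise to tensor emissions.
    """
    if emit not in ("st", "events", "frames"):
        raise ContractError(f"unknown emit mode {emit!r}")
    for c in classes:
        if c not in MOTION_CLASSES:
            raise ContractError(f"unknown motion class {c!r}")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_samples) % len(classes)
    rng.shuffle(labels)
    h, w = hw
    starts = rng.integers(0, [w if classes[c] in ("left", "right") else h
                              for c in labels])
    window = 1.0

    meta = {"starts": starts, "window": window, "t_steps": t_steps, "hw": hw}
    if emit == "frames":
        x = np.stack([
            motion_frames(classes[c], int(s), t_steps, hw)[:, None]
            for c, s in zip(labels, starts)
        ])
        return MotionDataset(y=labels, classes=tuple(classes), x=x, meta=meta)

    streams = [
        _frames_to_events(motion_frames(classes[c], int(s), t_steps, hw), window)
        for c, s in zip(labels, starts)
    ]
    if emit == "events":
        return MotionDataset(y=labels, classes=tuple(classes), events=streams,
                             meta=meta)
    x = np.concatenate([
        events_to_st(ev, window=window, t_steps=t_steps, binary=True)
        for ev in streams
    ])
    if noise_ratio > 0:
        x = add_background_noise(x, NoiseSpec(noise_ratio, seed=seed + 1))
    return MotionDataset(y=labels, classes=tuple(classes), x=x, meta=meta)
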