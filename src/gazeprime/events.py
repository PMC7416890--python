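"""Velocity-threshold (I-VT) parsing of raw samples into fixations.

Stands in for the eye tracker's online event parser.  Samples whose
smoothed speed stays below ``v_threshold`` form fixation candidates;
runs separated by gaps of at most ``merge_gap`` ms are merged (suppressing
noise blips) and runs shorter than ``min_duration`` ms are dropped.  Smooth
pursuit of slowly moving items stays below the default 30 deg/s threshold
and is deliberately classified as fixation — tracking a moving item is a
"fixation" on that item for the purposes of this analysis; the raw-sample
analysis path exists alongside precisely because classic parsers would not
count pursuit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gazesim import GazeStream

__all__ = [
    "FixationEvent",
    "ParserParams",
    "EmptyTrialError",
    "compute_velocity",
    "detect_fixations",
]


class EmptyTrialError(ValueError):
    """Fewer than two valid samples: the trial is excluded upstream."""


@dataclass(frozen=True)
class FixationEvent:
    """One fixation: [t_on, t_off) in ms, centroid in degrees."""

    t_on: float
    t_off: float
    cx: float
    cy: float

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


@dataclass(frozen=True)
class ParserParams:
    """Conventional I-VT defaults; all thresholds are configurable."""

    v_threshold: float = 30.0  # deg/s
    min_duration: float = 50.0  # ms
    merge_gap: float = 20.0  # ms
    smooth_window: int = 5  # samples, moving average on speed


def compute_velocity(stream: GazeStream) -> np.ndarray:
    """Per-sample gaze speed (deg/s): central differences, one-sided at the
    ends.  Invalid samples propagate as NaN to themselves and neighbours."""
    valid = np.asarray(stream.valid, dtype=bool)
    if valid.sum() < 2:
        raise EmptyTrialError("need at least two valid samples")
    t_s = np.asarray(stream.t, dtype=float) / 1000.0
    x = np.where(valid, stream.x, np.nan)
    y = np.where(valid, stream.y, np.nan)
    vx = np.gradient(x, t_s)
    vy = np.gradient(y, t_s)
    return np.hypot(vx, vy)


def _smooth(speed: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return speed
    kernel = np.ones(window) / window
    return np.convolve(speed, kernel, mode="same")


def detect_fixations(
    stream: GazeStream, params: ParserParams = ParserParams()
) -> list[FixationEvent]:
    """I-VT fixation detection on a raw stream.

    Maximal runs with smoothed speed below threshold become fixations with
    centroid = mean of member positions; an all-superthreshold stream yields
    an empty list.
    """
    speed = _smooth(compute_velocity(stream), params.smooth_window)
    below = np.asarray(stream.valid, dtype=bool) & (speed < params.v_threshold)
    if not below.any():
        return []

    t = np.asarray(stream.t, dtype=float)
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)  # inclusive index of run end
    if below[0]:
        starts = np.concatenate([[0], starts])
    if below[-1]:
        ends = np.concatenate([ends, [below.size - 1]])

    # merge runs separated by short gaps (noise blips, dropped samples)
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if t[s] - t[merged[-1][1]] - dt <= params.merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    out: list[FixationEvent] = []
    for s, e in merged:
        t_on, t_off = t[s], t[e] + dt
        if t_off - t_on < params.min_duration:
            continue
        member = np.zeros(below.size, dtype=bool)
        member[s : e + 1] = below[s : e + 1]
        out.append(
            FixationEvent(
                t_on=float(t_on),
                t_off=float(t_off),
                cx=float(np.mean(np.asarray(stream.x)[member])),
                cy=float(np.mean(np.asarray(stream.y)[member])),
            )
        )
    return out
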