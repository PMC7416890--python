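"""Synthetic 1000 Hz gaze streams over a trial's moving display.

There is no public gaze dataset for this paradigm, so the generator is the
package's stand-in for human observers: a minimal generative process built
from the same ingredients the analysis assumes.  Gaze alternates between
attentional episodes on single items (fixation or smooth pursuit, depending
on ``pursuit_gain``) and brief ballistic saccades between items.  Which item
an episode targets is a multinomial draw whose weight depends on the item's
match category against the trial's prime — equal weights give unbiased
("null") viewing, raising ``w_full`` biases gaze toward exact prime matches.

Measurement error follows the two error scales eye trackers quote: a
per-episode accuracy offset (sd ``noise_sd``, default 0.35 deg — mid-range
of typical video-tracker accuracy) and per-sample precision jitter (sd
``jitter_sd``, default 0.01 deg RMS).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .assign import MatchCategory, classify_match
from .stimulus import ItemType, Trajectories, TrialSpec

__all__ = ["BiasParams", "Episode", "GazeStream", "select_next_target", "simulate_trial_gaze"]

MIN_EPISODE_MS = 100.0  # >= 6 frames, so every episode is parseable


@dataclass(frozen=True)
class BiasParams:
    """Generator parameters; equal selection weights define the null model."""

    w_full: float = 1.0
    w_color: float = 1.0
    w_shape: float = 1.0
    w_none: float = 1.0
    fix_dur_mean: float = 400.0  # ms; with 30 ms saccades -> ~7 episodes / 3 s
    fix_dur_shape: float = 6.0  # gamma shape (dimensionless)
    noise_sd: float = 0.35  # deg, per-episode accuracy offset
    jitter_sd: float = 0.01  # deg, per-sample precision jitter
    pursuit_gain: float = 0.8  # 1 = perfect pursuit, 0 = static fixation
    saccade_dur: float = 30.0  # ms
    p_center_first: float = 0.9  # first episode targets screen center
    p_invalid: float = 0.0  # per-sample dropout, exercises exclusion rules

    def __post_init__(self) -> None:
        for name in ("w_full", "w_color", "w_shape", "w_none"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.pursuit_gain <= 1.0:
            raise ValueError("pursuit_gain must be in [0, 1]")

    def weight(self, category: MatchCategory) -> float:
        return {
            MatchCategory.FULL: self.w_full,
            MatchCategory.COLOR: self.w_color,
            MatchCategory.SHAPE: self.w_shape,
            MatchCategory.NONE: self.w_none,
        }[category]


@dataclass(frozen=True)
class Episode:
    """Ground-truth attentional episode; item None targets screen center."""

    t_on: float
    t_off: float
    item: int | None


@dataclass
class GazeStream:
    """Raw samples (ms from filler onset, degrees) plus ground-truth episodes."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    episodes: list[Episode] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.t.size


def select_next_target(
    current_item: int | None,
    frame_item_types: Sequence[ItemType],
    prime: ItemType,
    bias: BiasParams,
    rng: np.random.Generator,
) -> int:
    """Multinomial target draw over items, weighted by match category.

    The currently attended item is excluded, so under equal weights each of
    the 11 other items is chosen with probability 1/11.
    """
    w = np.array([bias.weight(classify_match(prime, t)) for t in frame_item_types])
    if current_item is not None:
        w[current_item] = 0.0
    return int(rng.choice(len(w), p=w / w.sum()))


def _truncated_gamma_ms(bias: BiasParams, rng: np.random.Generator) -> float:
    scale = bias.fix_dur_mean / bias.fix_dur_shape
    for _ in range(1000):
        d = rng.gamma(bias.fix_dur_shape, scale)
        if d >= MIN_EPISODE_MS:
            return d
    return MIN_EPISODE_MS


def _item_pos_at(traj: Trajectories, item: int, t_ms: np.ndarray, frame_rate: float) -> np.ndarray:
    """Item center at sample times, linearly interpolated between frames."""
    ff = np.asarray(t_ms, dtype=float) * frame_rate / 1000.0
    grid = np.arange(traj.n_frames, dtype=float)
    x = np.interp(ff, grid, traj.positions[item, :, 0])
    y = np.interp(ff, grid, traj.positions[item, :, 1])
    return np.column_stack([x, y])


def simulate_trial_gaze(
    spec: TrialSpec,
    traj: Trajectories,
    bias: BiasParams,
    rng: np.random.Generator,
) -> GazeStream:
    """Generate one trial's gaze stream spanning the full filler period.

    Episode durations are gamma(fix_dur_shape, fix_dur_mean/fix_dur_shape)
    truncated at 100 ms.  During an episode on item i the gaze follows
    pursuit_gain * item position + (1 - pursuit_gain) * position at episode
    onset, plus the episode's accuracy offset and per-sample jitter.
    Saccades last ``saccade_dur`` ms with linearly interpolated positions.
    The first episode targets the screen center with probability
    ``p_center_first``.  A final episode too short to parse is avoided by
    extending the previous one to the end of the trial.
    """
    n_ms = spec.duration_ms
    t = np.arange(n_ms, dtype=float)
    x = np.empty(n_ms)
    y = np.empty(n_ms)
    episodes: list[Episode] = []

    if rng.random() < bias.p_center_first:
        target: int | None = None
    else:
        target = select_next_target(None, traj.item_types, spec.prime, bias, rng)

    cursor = 0
    last_pos = np.zeros(2)
    while cursor < n_ms:
        dur = _truncated_gamma_ms(bias, rng)
        t_off = cursor + dur
        # never leave a terminal stub shorter than a parseable episode
        if t_off + bias.saccade_dur + MIN_EPISODE_MS > n_ms:
            t_off = n_ms
        t_off = min(t_off, n_ms)
        lo, hi = int(round(cursor)), int(round(t_off))
        ts = t[lo:hi]
        if target is None:
            track = np.zeros((ts.size, 2))
        else:
            item_pos = _item_pos_at(traj, target, ts, spec.frame_rate)
            anchor = _item_pos_at(traj, target, ts[:1], spec.frame_rate)[0]
            track = bias.pursuit_gain * item_pos + (1.0 - bias.pursuit_gain) * anchor
        offset = rng.normal(0.0, bias.noise_sd, size=2) if bias.noise_sd > 0 else np.zeros(2)
        jitter = (
            rng.normal(0.0, bias.jitter_sd, size=(ts.size, 2))
            if bias.jitter_sd > 0
            else 0.0
        )
        seg = track + offset + jitter
        x[lo:hi] = seg[:, 0]
        y[lo:hi] = seg[:, 1]
        episodes.append(Episode(float(lo), float(hi), target))
        last_pos = track[-1] + offset if ts.size else last_pos
        cursor = hi
        if cursor >= n_ms:
            break

        # saccade to the next target
        nxt = select_next_target(target, traj.item_types, spec.prime, bias, rng)
        s_hi = min(cursor + int(round(bias.saccade_dur)), n_ms)
        ts = t[cursor:s_hi]
        arrive = _item_pos_at(traj, nxt, np.array([float(s_hi)]), spec.frame_rate)[0]
        frac = (ts - cursor + 1.0) / (s_hi - cursor + 1.0)
        sx = last_pos[0] + frac * (arrive[0] - last_pos[0])
        sy = last_pos[1] + frac * (arrive[1] - last_pos[1])
        if bias.jitter_sd > 0:
            sx = sx + rng.normal(0.0, bias.jitter_sd, size=ts.size)
            sy = sy + rng.normal(0.0, bias.jitter_sd, size=ts.size)
        x[cursor:s_hi] = sx
        y[cursor:s_hi] = sy
        cursor = s_hi
        target = nxt

    valid = (
        rng.random(n_ms) >= bias.p_invalid
        if bias.p_invalid > 0
        else np.ones(n_ms, dtype=bool)
    )
    return GazeStream(t=t, x=x, y=y, valid=valid, episodes=episodes)
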