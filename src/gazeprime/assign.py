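"""Gaze-to-item assignment and match classification.

The scoring procedure at the heart of the analysis: on each display frame,
take one gaze point (the frame's first raw sample, or the active fixation's
centroid), find the nearest moving item by Euclidean distance to item
centers, and classify that item against the trial's prime as a full match
(same color and shape), color match, shape match, or no match.  Per-trial
category proportions are compared with the trial's chance levels — the
fraction of on-screen items in each category.

Chance levels are multiples of 2/12 because every display holds two copies
of each of its 6 types.  Their expectation over the uniform composition draw
has a closed form: (1/6, 5/24, 5/24, 5/12) when the prime is on screen and
(0, 1/4, 1/4, 1/2) when it is not; :func:`expected_chance` recomputes it by
exhaustive enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .stimulus import (
    ALL_ITEM_TYPES,
    DisplayComposition,
    ItemType,
    Trajectories,
    TrialSpec,
    iter_compositions,
)

if TYPE_CHECKING:  # pragma: no cover
    from .events import FixationEvent
    from .gazesim import GazeStream

__all__ = [
    "MatchCategory",
    "CATEGORIES",
    "TrialDistribution",
    "ChanceLevels",
    "classify_match",
    "category_counts",
    "samples_per_frame",
    "first_sample_per_frame",
    "nearest_item",
    "trial_distribution",
    "chance_levels",
    "expected_chance",
    "expected_chance_exact",
    "nth_fixation_categories",
]


class MatchCategory(Enum):
    FULL = "full"
    COLOR = "color"
    SHAPE = "shape"
    NONE = "none"


CATEGORIES: tuple[MatchCategory, ...] = (
    MatchCategory.FULL,
    MatchCategory.COLOR,
    MatchCategory.SHAPE,
    MatchCategory.NONE,
)
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


def classify_match(prime: ItemType, item: ItemType) -> MatchCategory:
    """Classify an item against the prime by shared color/shape features."""
    same_color = item.color == prime.color
    same_shape = item.shape == prime.shape
    if same_color and same_shape:
        return MatchCategory.FULL
    if same_color:
        return MatchCategory.COLOR
    if same_shape:
        return MatchCategory.SHAPE
    return MatchCategory.NONE


def category_indices(prime: ItemType, item_types: Sequence[ItemType]) -> np.ndarray:
    """Per-item category index (0=FULL..3=NONE) against the prime."""
    return np.array(
        [_CAT_INDEX[classify_match(prime, t)] for t in item_types], dtype=np.intp
    )


def category_counts(prime: ItemType, item_types: Sequence[ItemType]) -> np.ndarray:
    """Count items per category, ordered FULL, COLOR, SHAPE, NONE."""
    return np.bincount(category_indices(prime, item_types), minlength=4)


@dataclass
class TrialDistribution:
    """Observed per-category frame proportions for one trial.

    ``frames_used == 0`` marks an excluded trial (no usable gaze data);
    ``proportions`` is then all-NaN.
    """

    proportions: np.ndarray  # ordered FULL, COLOR, SHAPE, NONE
    frames_used: int
    basis: str  # "samples" | "fixations"

    @property
    def excluded(self) -> bool:
        return self.frames_used == 0

    def as_dict(self) -> dict[str, float]:
        return {c.value: float(p) for c, p in zip(CATEGORIES, self.proportions)}


@dataclass
class ChanceLevels:
    """Item-count fractions per category (counts / 12) for one composition."""

    proportions: np.ndarray  # ordered FULL, COLOR, SHAPE, NONE

    def as_dict(self) -> dict[str, float]:
        return {c.value: float(p) for c, p in zip(CATEGORIES, self.proportions)}


def samples_per_frame(sample_rate: float = 1000.0, frame_rate: float = 60.0) -> int:
    """Whole samples guaranteed to fall in every frame window (16 at 1000/60)."""
    return math.floor(sample_rate / frame_rate)


def first_sample_per_frame(stream: "GazeStream", spec: TrialSpec) -> np.ndarray:
    """Index of the earliest valid sample in each frame window, -1 if none.

    Frame ``f`` covers the half-open window [f/rate, (f+1)/rate) seconds; at
    nominal 1000 Hz / 60 Hz up to 16-17 samples land in a window and only the
    first is kept — consecutive within-frame samples are nearly identical.
    """
    t = np.asarray(stream.t, dtype=float)
    valid = np.asarray(stream.valid, dtype=bool)
    tv = t[valid]
    vidx = np.flatnonzero(valid)
    # multiply before dividing so exact-millisecond boundaries stay exact
    edges = np.arange(spec.n_frames + 1) * 1000.0 / spec.frame_rate
    first = np.searchsorted(tv, edges[:-1], side="left")
    out = np.full(spec.n_frames, -1, dtype=np.intp)
    has = first < tv.size
    has[has] = tv[first[has]] < edges[1:][has]
    out[has] = vidx[first[has]]
    return out


def nearest_item(point: Sequence[float], traj: Trajectories, frame: int) -> int:
    """Item whose center is closest to the point on that frame.

    Ties break to the lowest item id (np.argmin returns the first minimum).
    """
    d2 = np.sum((traj.positions[:, frame, :] - np.asarray(point)) ** 2, axis=1)
    return int(np.argmin(d2))


def _frames_and_points_samples(
    stream: "GazeStream", spec: TrialSpec
) -> tuple[np.ndarray, np.ndarray]:
    idx = first_sample_per_frame(stream, spec)
    frames = np.flatnonzero(idx >= 0)
    sel = idx[frames]
    pts = np.column_stack([np.asarray(stream.x)[sel], np.asarray(stream.y)[sel]])
    return frames, pts

def _frames_and_points_fixations(
    fixations: Sequence["FixationEvent"], spec: TrialSpec
) -> tuple[np.ndarray, np.ndarray]:
    # a frame belongs to the fixation active at the frame's onset time;
    # fixations are disjoint so at most one qualifies per frame
    frame_t = np.arange(spec.n_frames) * 1000.0 / spec.frame_rate
    frames, pts = [], []
    for fx in fixations:
        inside = np.flatnonzero((frame_t >= fx.t_on) & (frame_t < fx.t_off))
        frames.extend(inside.tolist())
        pts.extend([(fx.cx, fx.cy)] * inside.size)
    if not frames:
        return np.empty(0, dtype=np.intp), np.empty((0, 2))
    order = np.argsort(frames)
    return np.asarray(frames, dtype=np.intp)[order], np.asarray(pts)[order]


def trial_distribution(
    spec: TrialSpec,
    traj: Trajectories,
    stream: "GazeStream | None" = None,
    basis: str = "samples",
    fixations: Sequence["FixationEvent"] | None = None,
) -> TrialDistribution:
    """Observed category proportions over classified frames for one trial.

    basis="samples": one point per frame, the frame's first valid raw sample.
    basis="fixations": only frames covered by a fixation, using the fixation
    centroid as the point (re-compared to moving item positions each frame).
    A trial with zero classified frames is returned flagged excluded.
    """
    if basis == "samples":
        if stream is None:
            raise ValueError("samples basis requires a gaze stream")
        frames, pts = _frames_and_points_samples(stream, spec)
    elif basis == "fixations":
        if fixations is None:
            raise ValueError("fixations basis requires parsed fixations")
        frames, pts = _frames_and_points_fixations(fixations, spec)
    else:
        raise ValueError(f"unknown basis {basis!r}")

    if frames.size == 0:
        return TrialDistribution(np.full(4, np.nan), 0, basis)

    # (n_items, F) distances; argmin over items, first-minimum tie-break
    diff = traj.positions[:, frames, :] - pts[None, :, :]
    d2 = np.einsum("ifk,ifk->if", diff, diff)
    items = np.argmin(d2, axis=0)
    cats = category_indices(spec.prime, traj.item_types)[items]
    counts = np.bincount(cats, minlength=4)
    return TrialDistribution(counts / counts.sum(), int(frames.size), basis)


def chance_levels(composition: DisplayComposition) -> ChanceLevels:
    """Per-category item-count fractions: (2 x types in category) / 12."""
    counts = category_counts(composition.prime, composition.item_types)
    return ChanceLevels(counts / counts.sum())


def expected_chance_exact(prime_present: bool) -> dict[MatchCategory, Fraction]:
    """Expectation of chance levels over the uniform composition draw,
    by exhaustive enumeration of all 56 (present) or 28 (absent) equally
    likely compositions, in exact rational arithmetic."""
    prime = ALL_ITEM_TYPES[0]  # symmetric over primes
    totals = {c: Fraction(0) for c in CATEGORIES}
    n = 0
    for comp in iter_compositions(prime, prime_present):
        counts = category_counts(prime, comp.item_types)
        for c, k in zip(CATEGORIES, counts):
            totals[c] += Fraction(int(k), comp.n_items)
        n += 1
    return {c: totals[c] / n for c in CATEGORIES}


def expected_chance(prime_present: bool) -> ChanceLevels:
    exact = expected_chance_exact(prime_present)
    return ChanceLevels(np.array([float(exact[c]) for c in CATEGORIES]))


def nth_fixation_categories(
    spec: TrialSpec,
    fixations: Sequence["FixationEvent"],
    traj: Trajectories,
    n_max: int = 4,
) -> list[MatchCategory]:
    """Category of each of the first ``n_max`` fixations.

    Each fixation is scored per frame (nearest item to its centroid while
    items move) and aggregated by majority vote over items; ties go to the
    item of the earliest frame among those tied.  Returns one category per
    available rank; callers enforce the >= n_max inclusion rule.
    """
    frame_t = np.arange(spec.n_frames) * 1000.0 / spec.frame_rate
    cats = category_indices(spec.prime, traj.item_types)
    out: list[MatchCategory] = []
    for fx in fixations[:n_max]:
        frames = np.flatnonzero((frame_t >= fx.t_on) & (frame_t < fx.t_off))
        if frames.size == 0:
            continue
        diff = traj.positions[:, frames, :] - np.array([fx.cx, fx.cy])[None, None, :]
        d2 = np.einsum("ifk,ifk->if", diff, diff)
        items = np.argmin(d2, axis=0)
        counts = np.bincount(items, minlength=traj.n_items)
        best = counts.max()
        tied = set(np.flatnonzero(counts == best).tolist())
        winner = next(int(i) for i in items if int(i) in tied)
        out.append(CATEGORIES[cats[winner]])
    return out
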