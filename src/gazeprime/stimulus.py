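"""Trial specification: item taxonomy, display composition, and item motion.

A trial's moving "filler" display contains 12 colored shapes — two copies of
each of 6 item types drawn from the 3 colors x 3 shapes taxonomy.  On
prime-present trials the type shown in the preceding memory display (the
prime) is one of the 6; on prime-absent trials the 6 are drawn from the
remaining 8 types.  Items move at a fixed speed on straight paths with
specular reflection at the arena walls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Color",
    "Shape",
    "ItemType",
    "ALL_ITEM_TYPES",
    "DisplayComposition",
    "TrialSpec",
    "Trajectories",
    "ArenaTooSmallError",
    "sample_composition",
    "count_compositions",
    "iter_compositions",
    "simulate_motion",
    "generate_session",
]

# Display geometry in degrees of visual angle, origin at screen center,
# x rightward, y upward.
ARENA_WIDTH = 26.0
ARENA_HEIGHT = 20.0
ITEM_SIZE = 1.52
N_ITEMS = 12
COPIES_PER_TYPE = 2
TYPES_PER_DISPLAY = 6
DEFAULT_SPEED = 5.0  # deg/s; traverses a visible fraction of the arena in 3 s


class Color(str, Enum):
    RED = "red"
    GREEN = "green"
    BLUE = "blue"


class Shape(str, Enum):
    CIRCLE = "circle"
    SQUARE = "square"
    PLUS = "plus"


@dataclass(frozen=True, order=True)
class ItemType:
    """One of the 9 color x shape combinations; the unit of priming."""

    color: Color
    shape: Shape

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.color.value}-{self.shape.value}"


ALL_ITEM_TYPES: tuple[ItemType, ...] = tuple(
    ItemType(c, s) for c in Color for s in Shape
)


class ArenaTooSmallError(RuntimeError):
    """Raised when non-overlapping initial placement cannot be found."""


@dataclass(frozen=True)
class DisplayComposition:
    """The 6 item types shown (two copies each) and the trial's prime.

    ``prime_present`` is redundant with ``prime in types`` but stored
    explicitly as the trial's condition label; consistency is enforced.
    """

    types: tuple[ItemType, ...]
    prime: ItemType
    prime_present: bool
    copies_per_type: int = COPIES_PER_TYPE

    def __post_init__(self) -> None:
        if len(self.types) != TYPES_PER_DISPLAY:
            raise ValueError(f"expected {TYPES_PER_DISPLAY} types, got {len(self.types)}")
        if len(set(self.types)) != TYPES_PER_DISPLAY:
            raise ValueError("display types must be distinct")
        if (self.prime in self.types) != self.prime_present:
            raise ValueError("prime_present flag inconsistent with types")

    @property
    def n_items(self) -> int:
        return len(self.types) * self.copies_per_type

    @property
    def item_types(self) -> tuple[ItemType, ...]:
        """Per-item types, item ids 0..11: each display type repeated twice."""
        return tuple(t for t in self.types for _ in range(self.copies_per_type))

    @property
    def condition(self) -> str:
        return "prime_present" if self.prime_present else "prime_absent"


@dataclass(frozen=True)
class TrialSpec:
    trial_id: int
    subject_id: int
    prime: ItemType
    composition: DisplayComposition
    n_frames: int = 180
    frame_rate: float = 60.0
    sample_rate: float = 1000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.prime != self.composition.prime:
            raise ValueError("trial prime differs from composition prime")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def duration_ms(self) -> int:
        return round(1000.0 * self.n_frames / self.frame_rate)

    @property
    def condition(self) -> str:
        return self.composition.condition


@dataclass
class Trajectories:
    """Per-frame item center positions, degrees from screen center.

    positions has shape (n_items, n_frames, 2); item ``i`` carries type
    ``item_types[i]`` for the whole trial.
    """

    positions: np.ndarray
    item_types: tuple[ItemType, ...]
    speed: float
    arena: tuple[float, float] = (ARENA_WIDTH, ARENA_HEIGHT)
    item_size: float = ITEM_SIZE

    @property
    def n_items(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]


def sample_composition(
    prime: ItemType, prime_present: bool, rng: np.random.Generator
) -> DisplayComposition:
    """Draw a display composition uniformly under the trial's condition.

    Prime present: the prime plus 5 of the other 8 types, uniformly without
    replacement.  Prime absent: 6 of the 8 non-prime types.
    """
    others = [t for t in ALL_ITEM_TYPES if t != prime]
    if prime_present:
        picked = rng.choice(len(others), size=TYPES_PER_DISPLAY - 1, replace=False)
        types = (prime,) + tuple(others[i] for i in picked)
    else:
        picked = rng.choice(len(others), size=TYPES_PER_DISPLAY, replace=False)
        types = tuple(others[i] for i in picked)
    return DisplayComposition(types=tuple(sorted(types)), prime=prime,
                              prime_present=prime_present)


def count_compositions(n: int = 9, k: int = TYPES_PER_DISPLAY) -> int:
    """Number of k-subsets of n item types (default: 6 of the 9 types -> 84)."""
    return math.comb(n, k)


def iter_compositions(
    prime: ItemType, prime_present: bool
) -> Iterator[DisplayComposition]:
    """Enumerate every equally likely composition for the given condition."""
    others = [t for t in ALL_ITEM_TYPES if t != prime]
    if prime_present:
        for rest in combinations(others, TYPES_PER_DISPLAY - 1):
            yield DisplayComposition(tuple(sorted((prime,) + rest)), prime, True)
    else:
        for chosen in combinations(others, TYPES_PER_DISPLAY):
            yield DisplayComposition(tuple(sorted(chosen)), prime, False)


def _place_items(
    n: int, half_w: float, half_h: float, min_dist: float,
    rng: np.random.Generator, max_attempts: int = 10_000,
) -> np.ndarray:
    """Rejection-sample n centers with pairwise distance >= min_dist."""
    placed = np.empty((n, 2))
    count = 0
    attempts = 0
    while count < n:
        if attempts >= max_attempts:
            raise ArenaTooSmallError(
                f"could not place {n} items with spacing {min_dist} "
                f"in arena {2 * half_w} x {2 * half_h} after {max_attempts} attempts"
            )
        attempts += 1
        cand = np.array([rng.uniform(-half_w, half_w), rng.uniform(-half_h, half_h)])
        if count == 0 or np.all(
            np.hypot(*(placed[:count] - cand).T) >= min_dist
        ):
            placed[count] = cand
            count += 1
    return placed


def simulate_motion(
    composition: DisplayComposition,
    spec: TrialSpec,
    speed: float = DEFAULT_SPEED,
    rng: np.random.Generator | None = None,
    heading_jitter: float = 0.0,
) -> Trajectories:
    """Constant-speed linear motion with specular wall reflection.

    Initial positions are uniform in the arena (items fully inside) with
    pairwise center distance >= item size; headings are uniform in [0, 2pi).
    ``heading_jitter`` (rad, sd per frame) optionally perturbs headings.
    """
    if speed < 0:
        raise ValueError("speed must be non-negative")
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)

    n = composition.n_items
    # item fully inside the arena: centers live in the shrunken box
    half_w = (ARENA_WIDTH - ITEM_SIZE) / 2.0
    half_h = (ARENA_HEIGHT - ITEM_SIZE) / 2.0
    pos = _place_items(n, half_w, half_h, ITEM_SIZE, rng)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    vel = speed / spec.frame_rate * np.column_stack([np.cos(theta), np.sin(theta)])

    out = np.empty((n, spec.n_frames, 2))
    if heading_jitter == 0.0:
        # constant velocity + specular reflection has a closed form: fold the
        # unreflected path into [-b, b] as a triangle wave of period 4b
        f = np.arange(spec.n_frames)
        for axis, bound in ((0, half_w), (1, half_h)):
            raw = pos[:, None, axis] + vel[:, None, axis] * f[None, :]
            z = np.mod(raw + bound, 4.0 * bound)
            out[:, :, axis] = -bound + (2.0 * bound - np.abs(z - 2.0 * bound))
        return Trajectories(
            positions=out, item_types=composition.item_types, speed=speed
        )

    out[:, 0, :] = pos
    for f in range(1, spec.n_frames):
        if heading_jitter > 0.0:
            dphi = rng.normal(0.0, heading_jitter, size=n)
            c, s = np.cos(dphi), np.sin(dphi)
            vel = np.column_stack(
                [c * vel[:, 0] - s * vel[:, 1], s * vel[:, 0] + c * vel[:, 1]]
            )
        pos = pos + vel
        # specular reflection keeps the step length (energy) unchanged
        for axis, bound in ((0, half_w), (1, half_h)):
            over = pos[:, axis] > bound
            pos[over, axis] = 2.0 * bound - pos[over, axis]
            vel[over, axis] *= -1.0
            under = pos[:, axis] < -bound
            pos[under, axis] = -2.0 * bound - pos[under, axis]
            vel[under, axis] *= -1.0
        out[:, f, :] = pos

    return Trajectories(
        positions=out, item_types=composition.item_types, speed=speed
    )


def generate_session(
    n_trials: int = 180,
    p_prime_present: float = 0.5,
    rng: np.random.Generator | None = None,
    subject_id: int = 0,
) -> list[TrialSpec]:
    """Draw a session: per-trial prime uniform over the 9 types, condition
    Bernoulli(p_prime_present), and an independent per-trial motion seed."""
    if not 0.0 <= p_prime_present <= 1.0:
        raise ValueError("p_prime_present must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    trials = []
    for i in range(n_trials):
        prime = ALL_ITEM_TYPES[rng.integers(len(ALL_ITEM_TYPES))]
        present = bool(rng.random() < p_prime_present)
        comp = sample_composition(prime, present, rng)
        trials.append(
            TrialSpec(
                trial_id=i,
                subject_id=subject_id,
                prime=prime,
                composition=comp,
                rng_seed=int(rng.integers(2**31)),
            )
        )
    return trials
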