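"""End-to-end orchestration: simulate sessions, score trials, build tables.

Everything here is in-memory and deterministic: the master seed plus
(subject, trial) indices are fed to a numpy SeedSequence, so any trial can
be regenerated in isolation and identical configs produce identical tables.
The command-line layer and the analysis drivers are thin wrappers over
these functions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import assign, events, gazesim, stats, stimulus
from .assign import CATEGORIES
from .events import ParserParams
from .gazesim import BiasParams
from .stimulus import ALL_ITEM_TYPES, ItemType, TrialSpec

__all__ = [
    "RunConfig",
    "trial_rng",
    "simulate_trial",
    "score_trial",
    "run_subject",
    "run_experiment",
    "PER_TRIAL_COLUMNS",
    "RANK_COLUMNS",
]

_CAT_NAMES = [c.value for c in CATEGORIES]

PER_TRIAL_COLUMNS = (
    ["trial_id", "subject_id", "condition", "basis"]
    + [f"p_{c}" for c in _CAT_NAMES]
    + [f"chance_{c}" for c in _CAT_NAMES]
    + ["frames_used", "n_fixations"]
)
RANK_COLUMNS = (
    ["trial_id", "subject_id", "condition", "rank", "category"]
    + [f"chance_{c}" for c in _CAT_NAMES]
)


@dataclass(frozen=True)
class RunConfig:
    """Full parameterisation of a simulated experiment."""

    n_subjects: int = 12
    n_trials: int = 180
    p_prime_present: float = 0.5
    speed: float = stimulus.DEFAULT_SPEED
    heading_jitter: float = 0.0
    bias: BiasParams = field(default_factory=BiasParams)
    parser: ParserParams = field(default_factory=ParserParams)
    basis: tuple[str, ...] = ("samples", "fixations")
    n_max_ranks: int = 4
    seed: int = 0
    label: str = "exp1"

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be positive")
        if not 0.0 <= self.p_prime_present <= 1.0:
            raise ValueError("p_prime_present must be in [0, 1]")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        bad = set(self.basis) - {"samples", "fixations"}
        if bad:
            raise ValueError(f"unknown basis values: {sorted(bad)}")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["basis"] = list(self.basis)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "bias" in d:
            d["bias"] = BiasParams(**d["bias"])
        if "parser" in d:
            d["parser"] = ParserParams(**d["parser"])
        if "basis" in d:
            d["basis"] = tuple(d["basis"])
        return cls(**d)


def trial_rng(master_seed: int, subject_id: int, trial_id: int) -> np.random.Generator:
    """Per-trial generator derived from the master seed; reproducible in
    isolation."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(subject_id), int(trial_id)])
    )


def _session_specs(config: RunConfig, subject_id: int) -> list[TrialSpec]:
    rng = trial_rng(config.seed, subject_id, 2**31 - 1)  # session-level stream
    return stimulus.generate_session(
        n_trials=config.n_trials,
        p_prime_present=config.p_prime_present,
        rng=rng,
        subject_id=subject_id,
    )


def simulate_trial(
    spec: TrialSpec, config: RunConfig
) -> tuple[stimulus.Trajectories, gazesim.GazeStream]:
    """Trajectories plus raw gaze for one trial, from the trial's own rng."""
    rng = trial_rng(config.seed, spec.subject_id, spec.trial_id)
    traj = stimulus.simulate_motion(
        spec.composition, spec, speed=config.speed, rng=rng,
        heading_jitter=config.heading_jitter,
    )
    stream = gazesim.simulate_trial_gaze(spec, traj, config.bias, rng)
    return traj, stream


def score_trial(
    spec: TrialSpec,
    traj: stimulus.Trajectories,
    stream: gazesim.GazeStream,
    config: RunConfig,
) -> tuple[list[dict], list[dict]]:
    """Per-trial result rows (one per basis) and rank records.

    Excluded trials (no classifiable gaze) are emitted with frames_used = 0.
    """
    cha = assign.chance_levels(spec.composition).proportions
    chance_cols = {f"chance_{c}": float(v) for c, v in zip(_CAT_NAMES, cha)}

    fixations: list[events.FixationEvent] = []
    if "fixations" in config.basis:
        try:
            fixations = events.detect_fixations(stream, config.parser)
        except events.EmptyTrialError:
            fixations = []

    rows: list[dict] = []
    for basis in config.basis:
        dist = assign.trial_distribution(
            spec, traj, stream=stream, basis=basis, fixations=fixations
        )
        props = dist.proportions
        rows.append(
            {
                "trial_id": spec.trial_id,
                "subject_id": spec.subject_id,
                "condition": spec.condition,
                "basis": basis,
                **{f"p_{c}": float(v) for c, v in zip(_CAT_NAMES, props)},
                **chance_cols,
                "frames_used": dist.frames_used,
                "n_fixations": len(fixations),
            }
        )

    rank_rows: list[dict] = []
    if "fixations" in config.basis and len(fixations) >= config.n_max_ranks:
        cats = assign.nth_fixation_categories(
            spec, fixations, traj, n_max=config.n_max_ranks
        )
        for rank, cat in enumerate(cats, start=1):
            rank_rows.append(
                {
                    "trial_id": spec.trial_id,
                    "subject_id": spec.subject_id,
                    "condition": spec.condition,
                    "rank": rank,
                    "category": cat.value,
                    **chance_cols,
                }
            )
    return rows, rank_rows


def run_subject(
    config: RunConfig, subject_id: int
) -> tuple[list[dict], list[dict]]:
    rows: list[dict] = []
    rank_rows: list[dict] = []
    for spec in _session_specs(config, subject_id):
        traj, stream = simulate_trial(spec, config)
        r, rr = score_trial(spec, traj, stream, config)
        rows.extend(r)
        rank_rows.extend(rr)
    return rows, rank_rows


def run_experiment(
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate and score the whole design.

    Returns (per_trial, rank_records, summary): per-trial proportions and
    chance, per-rank fixation categories, and the condition x category test
    table (including per-rank blocks when fixations are analysed).
    """
    rows: list[dict] = []
    rank_rows: list[dict] = []
    for subject_id in range(config.n_subjects):
        r, rr = run_subject(config, subject_id)
        rows.extend(r)
        rank_rows.extend(rr)
    per_trial = pd.DataFrame(rows, columns=PER_TRIAL_COLUMNS)
    rank_records = pd.DataFrame(rank_rows, columns=RANK_COLUMNS)
    summary = stats.analyze_experiment(per_trial)
    if not rank_records.empty:
        summary = pd.concat(
            [summary, stats.analyze_nth_fixations(rank_records, config.n_max_ranks)],
            ignore_index=True,
        )
    return per_trial, rank_records, summary
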