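"""Subject-level aggregation and paired comparisons against chance.

Per-trial category proportions and their trial-specific chance levels are
averaged within subject (over non-excluded trials), arcsine-transformed
(arcsin sqrt p, the variance-stabiliser for count proportions), and compared
with a paired t-test that treats chance as the second member of each pair —
chance varies from trial to trial with the drawn composition, so it carries
sampling variance of its own and a one-sample test against a constant would
be wrong.  Effect size is paired Cohen's d = mean(diff) / sd(diff).  Tests
run on transformed values; reported means are untransformed.  Two-sided
p-values, no multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assign import CATEGORIES

__all__ = [
    "PairedTestResult",
    "arcsine_transform",
    "paired_t_vs_chance",
    "subject_summaries",
    "analyze_experiment",
    "analyze_nth_fixations",
]

logger = logging.getLogger(__name__)

_CAT_NAMES = [c.value for c in CATEGORIES]
_OBS_COLS = [f"p_{c}" for c in _CAT_NAMES]
_CHANCE_COLS = [f"chance_{c}" for c in _CAT_NAMES]

SUMMARY_COLUMNS = [
    "condition", "basis", "rank", "category",
    "mean_observed", "mean_chance", "t", "df", "p", "cohen_d", "n_subjects",
]


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    d: float
    n_subjects: int


def arcsine_transform(p):
    """arcsin(sqrt(p)); maps [0, 1] to [0, pi/2]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return out if out.ndim else float(out)


def paired_t_vs_chance(observed, chance) -> PairedTestResult:
    """Paired t on (observed - chance) with df = n - 1.

    Inputs are per-subject values (already transformed by the caller when
    used in the main analysis).  Zero-variance differences give t = 0, p = 1
    when all differences are zero and t = +/-inf, p = 0 otherwise.
    """
    obs = np.asarray(observed, dtype=float)
    cha = np.asarray(chance, dtype=float)
    if obs.shape != cha.shape or obs.ndim != 1:
        raise ValueError("observed and chance must be equal-length vectors")
    n = obs.size
    if n < 2:
        raise ValueError("need at least two subjects")
    diff = obs - cha
    m = diff.mean()
    sd = diff.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if m == 0.0:
            return PairedTestResult(0.0, df, 1.0, 0.0, n)
        t = np.inf if m > 0 else -np.inf
        return PairedTestResult(float(t), df, 0.0, float(np.sign(m)) * np.inf, n)
    t = m / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTestResult(float(t), df, float(p), float(m / sd), n)


def subject_summaries(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, condition, basis) mean observed and chance proportions
    over non-excluded trials."""
    ok = per_trial[per_trial["frames_used"] > 0]
    grouped = (
        ok.groupby(["subject_id", "condition", "basis"], sort=True)[
            _OBS_COLS + _CHANCE_COLS
        ]
        .mean()
        .reset_index()
    )
    grouped["n_trials"] = (
        ok.groupby(["subject_id", "condition", "basis"], sort=True)
        .size()
        .to_numpy()
    )
    return grouped


def _test_rows(
    summaries: pd.DataFrame, basis: str, rank: str = "all"
) -> list[dict]:
    rows: list[dict] = []
    for condition, grp in summaries.groupby("condition", sort=True):
        if len(grp) < 2:
            logger.warning(
                "condition %r has %d subject(s); omitted from tests",
                condition, len(grp),
            )
            continue
        for cat in _CAT_NAMES:
            obs = grp[f"p_{cat}"].to_numpy()
            cha = grp[f"chance_{cat}"].to_numpy()
            res = paired_t_vs_chance(arcsine_transform(obs), arcsine_transform(cha))
            rows.append(
                {
                    "condition": condition,
                    "basis": basis,
                    "rank": rank,
                    "category": cat,
                    "mean_observed": obs.mean(),
                    "mean_chance": cha.mean(),
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "cohen_d": res.d,
                    "n_subjects": res.n_subjects,
                }
            )
    return rows


def analyze_experiment(per_trial: pd.DataFrame, basis: str | None = None) -> pd.DataFrame:
    """One row per (condition, category, basis): subject-mean observed and
    chance proportions with the paired test on transformed values.

    ``per_trial`` columns: subject_id, condition, basis, p_*, chance_*,
    frames_used (excluded trials have frames_used = 0 and never enter means).
    """
    if basis is not None:
        per_trial = per_trial[per_trial["basis"] == basis]
    rows: list[dict] = []
    for b, sub in per_trial.groupby("basis", sort=True):
        rows.extend(_test_rows(subject_summaries(sub), basis=str(b)))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def analyze_nth_fixations(rank_records: pd.DataFrame, n_max: int = 4) -> pd.DataFrame:
    """Order-of-fixation analysis: per (rank, condition, category), the
    subject-mean proportion of trials whose rank-n fixation landed in the
    category, against subject-mean chance.

    ``rank_records`` has one row per (trial, rank) for trials with at least
    ``n_max`` fixations: subject_id, condition, trial_id, rank, category,
    chance_full..chance_none.
    """
    rows: list[dict] = []
    recs = rank_records[rank_records["rank"] <= n_max]
    for rank, at_rank in recs.groupby("rank", sort=True):
        per_subj = []
        for (subj, cond), grp in at_rank.groupby(["subject_id", "condition"], sort=True):
            entry = {"subject_id": subj, "condition": cond}
            n = len(grp)
            for cat in _CAT_NAMES:
                entry[f"p_{cat}"] = float((grp["category"] == cat).sum()) / n
                entry[f"chance_{cat}"] = grp[f"chance_{cat}"].mean()
            per_subj.append(entry)
        summaries = pd.DataFrame(per_subj)
        rows.extend(_test_rows(summaries, basis="fixations", rank=str(rank)))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
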