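"""Plain-text file formats for every pipeline stage.

All formats are round-trippable: whatever the pipeline writes it can read
back bit-for-bit into equivalent objects.  Positions are written with fixed
decimal precision so identical runs produce byte-identical files.

- trial metadata: JSON list of trials (prime, composition, condition, seed)
- trajectories:   TSV trial_id, frame, item_id, color, shape, x_deg, y_deg
- raw samples:    TSV trial_id, t_ms, x_deg, y_deg, valid
- fixation events: TSV trial_id, t_on_ms, t_off_ms, cx_deg, cy_deg
- per-trial results: TSV (see pipeline.PER_TRIAL_COLUMNS)
- summaries:      CSV (see stats.SUMMARY_COLUMNS)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .events import FixationEvent
from .gazesim import GazeStream
from .stimulus import (
    Color,
    DisplayComposition,
    ItemType,
    Shape,
    Trajectories,
    TrialSpec,
)

__all__ = [
    "write_trial_metadata", "read_trial_metadata",
    "write_trajectories", "read_trajectories",
    "write_samples", "read_samples",
    "write_events", "read_events",
    "write_table", "read_table",
]

_FLOAT_FMT = "%.5f"


def _item_to_dict(t: ItemType) -> dict:
    return {"color": t.color.value, "shape": t.shape.value}


def _item_from_dict(d: dict) -> ItemType:
    return ItemType(Color(d["color"]), Shape(d["shape"]))


def write_trial_metadata(path: str | Path, specs: Sequence[TrialSpec]) -> None:
    payload = [
        {
            "trial_id": s.trial_id,
            "subject_id": s.subject_id,
            "prime": _item_to_dict(s.prime),
            "composition": [_item_to_dict(t) for t in s.composition.types],
            "condition": s.condition,
            "n_frames": s.n_frames,
            "frame_rate": s.frame_rate,
            "sample_rate": s.sample_rate,
            "seed": s.rng_seed,
        }
        for s in specs
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_trial_metadata(path: str | Path) -> list[TrialSpec]:
    payload = json.loads(Path(path).read_text())
    specs = []
    for d in payload:
        prime = _item_from_dict(d["prime"])
        types = tuple(sorted(_item_from_dict(x) for x in d["composition"]))
        comp = DisplayComposition(
            types=types, prime=prime, prime_present=d["condition"] == "prime_present"
        )
        specs.append(
            TrialSpec(
                trial_id=d["trial_id"],
                subject_id=d["subject_id"],
                prime=prime,
                composition=comp,
                n_frames=d["n_frames"],
                frame_rate=d["frame_rate"],
                sample_rate=d["sample_rate"],
                rng_seed=d["seed"],
            )
        )
    return specs


def write_trajectories(
    path: str | Path, trials: Sequence[tuple[int, Trajectories]], mode: str = "w"
) -> None:
    """Write (trial_id, Trajectories) pairs as one long-format TSV."""
    chunks = []
    for trial_id, traj in trials:
        n_items, n_frames = traj.n_items, traj.n_frames
        item_ids = np.repeat(np.arange(n_items), n_frames)
        chunks.append(
            pd.DataFrame(
                {
                    "trial_id": trial_id,
                    "frame": np.tile(np.arange(n_frames), n_items),
                    "item_id": item_ids,
                    "color": [traj.item_types[i].color.value for i in item_ids],
                    "shape": [traj.item_types[i].shape.value for i in item_ids],
                    "x_deg": traj.positions[:, :, 0].ravel(),
                    "y_deg": traj.positions[:, :, 1].ravel(),
                }
            )
        )
    df = pd.concat(chunks, ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, mode=mode,
              header=mode == "w")


def read_trajectories(path: str | Path, speed: float) -> dict[int, Trajectories]:
    df = pd.read_csv(path, sep="\t")
    out: dict[int, Trajectories] = {}
    for trial_id, grp in df.groupby("trial_id", sort=True):
        n_items = int(grp["item_id"].max()) + 1
        n_frames = int(grp["frame"].max()) + 1
        pos = np.empty((n_items, n_frames, 2))
        g = grp.sort_values(["item_id", "frame"])
        pos[:, :, 0] = g["x_deg"].to_numpy().reshape(n_items, n_frames)
        pos[:, :, 1] = g["y_deg"].to_numpy().reshape(n_items, n_frames)
        first = g.drop_duplicates("item_id").sort_values("item_id")
        types = tuple(
            ItemType(Color(c), Shape(s))
            for c, s in zip(first["color"], first["shape"])
        )
        out[int(trial_id)] = Trajectories(positions=pos, item_types=types, speed=speed)
    return out


def write_samples(
    path: str | Path, trials: Sequence[tuple[int, GazeStream]]
) -> None:
    chunks = [
        pd.DataFrame(
            {
                "trial_id": trial_id,
                "t_ms": stream.t.astype(int),
                "x_deg": stream.x,
                "y_deg": stream.y,
                "valid": stream.valid.astype(int),
            }
        )
        for trial_id, stream in trials
    ]
    pd.concat(chunks, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_samples(path: str | Path) -> dict[int, GazeStream]:
    df = pd.read_csv(path, sep="\t")
    out: dict[int, GazeStream] = {}
    for trial_id, grp in df.groupby("trial_id", sort=True):
        g = grp.sort_values("t_ms")
        out[int(trial_id)] = GazeStream(
            t=g["t_ms"].to_numpy(dtype=float),
            x=g["x_deg"].to_numpy(),
            y=g["y_deg"].to_numpy(),
            valid=g["valid"].to_numpy(dtype=bool),
        )
    return out


def write_events(
    path: str | Path, trials: Sequence[tuple[int, Sequence[FixationEvent]]]
) -> None:
    rows = [
        {
            "trial_id": trial_id,
            "t_on_ms": fx.t_on,
            "t_off_ms": fx.t_off,
            "cx_deg": fx.cx,
            "cy_deg": fx.cy,
        }
        for trial_id, fixations in trials
        for fx in fixations
    ]
    pd.DataFrame(
        rows, columns=["trial_id", "t_on_ms", "t_off_ms", "cx_deg", "cy_deg"]
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_events(path: str | Path) -> dict[int, list[FixationEvent]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[int, list[FixationEvent]] = {}
    for trial_id, grp in df.groupby("trial_id", sort=True):
        out[int(trial_id)] = [
            FixationEvent(r.t_on_ms, r.t_off_ms, r.cx_deg, r.cy_deg)
            for r in grp.sort_values("t_on_ms").itertuples()
        ]
    return out


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    """Per-trial tables as TSV, summary tables as CSV, by extension."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith(".tsv") else ","
    return pd.read_csv(path, sep=sep)
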