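"""Simulate two gaze datasets: an unbiased (null) observer and a primed one.

Both use the default study design scaled to 6 subjects x 60 trials so the
raw files stay small: a 3-s, 60 Hz, 180-frame display of 12 moving items
sampled at 1000 Hz.  The null observer selects items with equal weights;
the primed observer up-weights exact prime matches (w_full = 8).  Raw
session files (trial metadata JSON, trajectory TSV, sample TSV) are bulky
and land under scratch/sessions/; downstream tables go to results/.
"""

import dataclasses
from pathlib import Path

from click.testing import CliRunner

from gazeprime.cli import main as cli
from gazeprime.gazesim import BiasParams
from gazeprime.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent
SESSIONS = ROOT / "scratch" / "sessions"

BASE = RunConfig(n_subjects=6, n_trials=60, seed=2024)
CONDITIONS = {
    "null": BASE,
    "biased": dataclasses.replace(BASE, bias=BiasParams(w_full=8.0)),
}


def main() -> None:
    runner = CliRunner()
    for name, cfg in CONDITIONS.items():
        out = SESSIONS / name
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(cfg.to_yaml())
        res = runner.invoke(
            cli, ["simulate", "--config", str(out / "config.yaml"),
                  "--out", str(out)],
            catch_exceptions=False,
        )
        print(f"[{name}] {res.output.strip()}")


if __name__ == "__main__":
    main()
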