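"""Score the simulated sessions: parse, assign, and test against chance.

Reads the raw sessions written by 02_simulate.py, runs the full analysis
(I-VT parsing, per-frame nearest-item assignment on both the raw-sample and
fixation bases, order-of-fixation analysis, arcsine + paired-t statistics)
and writes the summary tables to results/summary_null.csv and
results/summary_biased.csv.  Expect the null session to show no reliable
deviations from chance, and the biased session to show full-match dwell
above chance with no-match dwell below it on prime-present trials.
"""

from pathlib import Path

from click.testing import CliRunner

from gazeprime import io
from gazeprime.cli import main as cli

ROOT = Path(__file__).resolve().parent.parent
SESSIONS = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"


def main() -> None:
    runner = CliRunner()
    RESULTS.mkdir(exist_ok=True)
    for name in ("null", "biased"):
        session = SESSIONS / name
        if not session.exists():
            raise SystemExit(f"run analysis/02_simulate.py first ({session} missing)")
        out = ROOT / "scratch" / "analysis" / name
        res = runner.invoke(
            cli, ["analyze", "--session", str(session), "--out", str(out)],
            catch_exceptions=False,
        )
        print(f"[{name}] {res.output.strip()}")
        summary = io.read_table(out / "summary.csv")
        summary.to_csv(RESULTS / f"summary_{name}.csv", index=False)
        overall = summary[(summary["rank"] == "all")
                          & (summary["condition"] == "prime_present")]
        for _, row in overall.iterrows():
            sig = "significant" if row["p"] < 0.05 else "n.s."
            print(f"  [{name}] {row['basis']:>9} {row['category']:>6}: "
                  f"obs {row['mean_observed']:.3f} vs chance "
                  f"{row['mean_chance']:.3f}  t({int(row['df'])})="
                  f"{row['t']:+.2f}, p={row['p']:.3g} ({sig})")


if __name__ == "__main__":
    main()
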