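"""Render the summary tables as text reports with significance markers.

Writes results/report_null.txt and results/report_biased.txt; the null
report should carry no stars anywhere, the biased report should star the
full-match (above chance) and no-match (below chance) rows on prime-present
trials.
"""

from pathlib import Path

from gazeprime import io
from gazeprime.cli import format_report

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    for name in ("null", "biased"):
        src = RESULTS / f"summary_{name}.csv"
        if not src.exists():
            raise SystemExit(f"run analysis/03_analyze.py first ({src} missing)")
        text = format_report(io.read_table(src))
        (RESULTS / f"report_{name}.txt").write_text(text)
        print(f"=== {name} ===")
        print(text)


if __name__ == "__main__":
    main()
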