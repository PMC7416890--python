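"""Enumerate the display-composition space and derive chance levels.

Counts the 6-of-9 composition space (84 displays; 56 once a prime is forced
in, 28 once it is excluded) and averages the per-display chance levels over
every equally likely composition, confirming the closed forms
(1/6, 5/24, 5/24, 5/12) prime-present and (0, 1/4, 1/4, 1/2) prime-absent.
Writes results/chance_levels.csv.
"""

from pathlib import Path

import pandas as pd

from gazeprime.assign import CATEGORIES, chance_levels, expected_chance_exact
from gazeprime.stimulus import (
    ALL_ITEM_TYPES,
    count_compositions,
    iter_compositions,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    prime = ALL_ITEM_TYPES[0]
    n_total = count_compositions()
    n_present = sum(1 for _ in iter_compositions(prime, True))
    n_absent = sum(1 for _ in iter_compositions(prime, False))
    print(f"composition space: {n_total} displays "
          f"({n_present} prime-present, {n_absent} prime-absent)")

    rows = []
    for flag, label in ((True, "prime_present"), (False, "prime_absent")):
        exact = expected_chance_exact(flag)
        print(f"expected chance, {label}: "
              + ", ".join(f"{c.value}={exact[c]}" for c in CATEGORIES))
        for c in CATEGORIES:
            rows.append({
                "condition": label, "category": c.value,
                "expected_chance": float(exact[c]),
                "exact": str(exact[c]),
            })
        # range of per-display chance across the enumeration
        per_display = [
            chance_levels(comp).proportions
            for comp in iter_compositions(prime, flag)
        ]
        lo = [min(p[i] for p in per_display) for i in range(4)]
        hi = [max(p[i] for p in per_display) for i in range(4)]
        print(f"  per-display range: "
              + ", ".join(f"{c.value} [{l:.3f},{h:.3f}]"
                          for c, l, h in zip(CATEGORIES, lo, hi)))

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "chance_levels.csv", index=False)
    print(f"wrote {OUT / 'chance_levels.csv'}")


if __name__ == "__main__":
    main()
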