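"""Deyo comorbidity breakdown among older non-DOA/DBA patients: per-category
visit and 28-day-death changes in 2020 wave and non-wave periods versus the
2016-2019 same-window baseline.

Reads results/data/records.csv; writes results/fig4_analog.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ed_avoidance.cli import RunConfig, run_comorbidity


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = run_comorbidity(args.out / "data" / "records.csv", RunConfig(), args.out)
    wave = table[table.phase == "wave"].sort_values("death_pct", ascending=False)
    print("2020 wave-period changes by comorbidity (visits vs deaths):")
    for row in wave.itertuples():
        death = f"{row.death_pct:+.1f}%" if pd.notna(row.death_pct) else "n/a"
        print(f"  {row.category:>28}: visits {row.visit_pct:+.1f}%  deaths {death}")


if __name__ == "__main__":
    main()
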