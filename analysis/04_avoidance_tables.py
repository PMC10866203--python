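"""Descriptive avoidance analytics: DOA/DBA vs non-DOA/DBA death changes by
wave/non-wave period, and the individual-level incidence-rate comparison of
DOA/DBA decedents (pandemic vs pre-pandemic groups, two-proportion z tests).

Reads results/data/records.csv; writes results/{table2_analog.csv,
table3_analog.csv}.
"""

import argparse
from pathlib import Path

import pandas as pd

from ed_avoidance.cli import RunConfig, run_doa_dba


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    run_doa_dba(args.out / "data" / "records.csv", RunConfig(), args.out)
    t2 = pd.read_csv(args.out / "table2_analog.csv")
    print("28-day death changes among >=65 (vs same-window baseline):")
    for row in t2.itertuples():
        kind = "DOA/DBA" if row.doa_dba else "non-DOA/DBA"
        pct = f"{row.pct_change:+.1f}%" if pd.notna(row.pct_change) else "n/a"
        print(f"  {row.year} {kind:>12} {row.phase:>7}: {row.change:+7.1f} ({pct})")
    t3 = pd.read_csv(args.out / "table3_analog.csv")
    print("\nincidence-rate categories, pandemic vs pre-pandemic decedents:")
    for row in t3.itertuples():
        p = "n/a" if pd.isna(row.p) else f"{row.p:.3g}"
        print(
            f"  {row.category:>10}: {row.covid}/{row.covid_total} vs "
            f"{row.pre_covid}/{row.pre_covid_total} (p={p})"
        )


if __name__ == "__main__":
    main()
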