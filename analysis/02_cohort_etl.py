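"""Cohort ETL: exclude COVID-PCR-positive visits, tally per-stratum daily
visits and 28-day deaths (by last visit date), and apply the sparse-stratum
exclusion (mean daily deaths <= 1).

Reads results/data/records.csv; writes results/{series.csv, etl_report.json}.
"""

import argparse
from pathlib import Path

from ed_avoidance.cli import RunConfig, run_etl


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    report = run_etl(args.out / "data" / "records.csv", RunConfig(), args.out)
    print(
        f"tallied {report['n_records']:,} records; "
        f"{report['n_covid_excluded']} COVID-positive excluded"
    )
    print(f"retained strata: {', '.join(report['retained_strata'])}")
    print(f"dropped (mean daily deaths <= 1): {', '.join(report['dropped_strata'])}")


if __name__ == "__main__":
    main()
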