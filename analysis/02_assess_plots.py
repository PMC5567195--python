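#!/usr/bin/env python
"""Classify every simulated plot (FV/U1/U2) and tally statuses by observer group.

Reads the surveys written by 01_simulate_surveys.py, runs the three-criterion
plot assessment and writes one assessment CSV per habitat plus a combined
tally table (results/assessment/status_tallies.csv).  The printed tallies
show the expected contrast: experts, who sample the patch core and detect
more items, classify most plots FV, while non-experts -- sampling degraded
edge conditions with lower detection -- classify most plots U1 or U2.
"""

import argparse
from pathlib import Path

import pandas as pd

from habstat.io import assessment_table, read_plot_records, read_protocol
from habstat.quality import SurveyDataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--surveys", type=Path, default=ROOT / "results" / "surveys")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "assessment")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    tallies = []
    for survey_dir in sorted(args.surveys.iterdir()):
        protocol = read_protocol(survey_dir / "protocol.yaml")
        plots = read_plot_records(survey_dir / "plot_records.csv")
        dataset = SurveyDataset(
            site_code="SITE",
            habitat_code=protocol.habitat_code,
            plots=plots,
            protocol=protocol,
        )
        table = assessment_table(dataset)
        table.to_csv(args.out_dir / f"assessment_{protocol.habitat_code}.csv", index=False)
        tally = (
            table.groupby(["observer_status", "overall_status"])
            .size()
            .rename("n_plots")
            .reset_index()
        )
        tally.insert(0, "habitat_code", protocol.habitat_code)
        tallies.append(tally)
        print(f"habitat {protocol.habitat_code}:")
        for _, row in tally.iterrows():
            print(
                f"  {row['observer_status']:>10} {row['overall_status']}: "
                f"{row['n_plots']} plots"
            )

    pd.concat(tallies).to_csv(args.out_dir / "status_tallies.csv", index=False)
    print(f"\ntallies -> {args.out_dir / 'status_tallies.csv'}")


if __name__ == "__main__":
    main()
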