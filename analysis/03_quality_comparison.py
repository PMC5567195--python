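#!/usr/bin/env python
"""Compare non-expert with expert records per habitat and item kind.

For each habitat and each of the three record kinds (structures & functions,
typical species, pressures & threats) this computes per-plot and pooled
completeness, accuracy, the shared / expert-only / non-expert-only item
partition and the low-support flags, and writes one JSON per habitat plus a
combined CSV of the headline metrics.  The pattern to look for: per-plot
completeness well below 1 (individual non-experts see less), pooled
completeness near or above 1 (the crowd jointly recovers what the experts
recorded), accuracy high, and a few singleton items flagged.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from habstat.io import read_plot_records, read_protocol
from habstat.quality import ITEM_KINDS, SurveyDataset, compare_groups

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--surveys", type=Path, default=ROOT / "results" / "surveys")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "quality")
    parser.add_argument("--min-observers", type=int, default=2)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for survey_dir in sorted(args.surveys.iterdir()):
        protocol = read_protocol(survey_dir / "protocol.yaml")
        dataset = SurveyDataset(
            site_code="SITE",
            habitat_code=protocol.habitat_code,
            plots=read_plot_records(survey_dir / "plot_records.csv"),
            protocol=protocol,
        )
        reports = {
            kind: compare_groups(dataset, kind, min_observers=args.min_observers)
            for kind in ITEM_KINDS
        }
        out = args.out_dir / f"quality_{protocol.habitat_code}.json"
        out.write_text(
            json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=2) + "\n"
        )
        for kind, r in reports.items():
            rows.append(
                {
                    "habitat_code": protocol.habitat_code,
                    "item_kind": kind,
                    "completeness_per_plot": round(r.completeness_per_plot, 3),
                    "completeness_pooled": round(r.completeness_pooled, 3),
                    "accuracy": round(r.accuracy, 3),
                    "n_only_nonexperts": len(r.items_only_nonexperts),
                    "n_flagged": len(r.flagged_items),
                }
            )
            print(
                f"habitat {protocol.habitat_code} {kind}: per-plot completeness "
                f"{r.completeness_per_plot:.2f}, pooled {r.completeness_pooled:.2f}, "
                f"accuracy {r.accuracy:.2f}, flagged {sorted(r.flagged_items)}"
            )

    pd.DataFrame(rows).to_csv(args.out_dir / "quality_summary.csv", index=False)
    print(f"\nsummary -> {args.out_dir / 'quality_summary.csv'}")


if __name__ == "__main__":
    main()
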