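#!/usr/bin/env python
"""Quantify plot-placement edge bias per habitat.

For each simulated survey, compares the mean distance from expert and
non-expert plot locations to the habitat-patch boundary with a two-sided
permutation test (5000 permutations).  Writes results/spatial/edge_bias.json.
Expected: non-expert plots lie a few metres from the edge while expert plots
sit tens of metres into the core, with small p-values throughout.
"""

import argparse
import json
from pathlib import Path

from habstat.io import read_plot_records, read_polygon, read_protocol
from habstat.quality import SurveyDataset
from habstat.spatial import compare_edge_distance

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--surveys", type=Path, default=ROOT / "results" / "surveys")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "spatial")
    parser.add_argument("--n-permutations", type=int, default=5000)
    parser.add_argument("--seed", type=int, default=20260924)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    results = {}
    for survey_dir in sorted(args.surveys.iterdir()):
        protocol = read_protocol(survey_dir / "protocol.yaml")
        dataset = SurveyDataset(
            site_code="SITE",
            habitat_code=protocol.habitat_code,
            plots=read_plot_records(survey_dir / "plot_records.csv"),
            protocol=protocol,
        )
        polygon = read_polygon(survey_dir / "patch.geojson")
        edge = compare_edge_distance(
            dataset, polygon, n_permutations=args.n_permutations, seed=args.seed
        )
        results[protocol.habitat_code] = edge.to_dict()
        print(
            f"habitat {protocol.habitat_code}: expert mean {edge.mean_dist_expert:5.1f} m, "
            f"non-expert mean {edge.mean_dist_nonexpert:5.1f} m, p = {edge.p_value:.4f}"
        )

    out = args.out_dir / "edge_bias.json"
    out.write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
    print(f"\nedge comparisons -> {out}")


if __name__ == "__main__":
    main()
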