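"""Readers/writers for the pipeline's file formats, and the pipeline driver.

Formats
-------
* habitat protocol: YAML (``habitat_code``; ``sf_checklist`` as
  ``[{id, label, class}]``; ``typical_species`` as
  ``[{id, weight, growth_form}]``; ``pressure_catalogue`` as
  ``[{code, label}]``);
* plot records: long-format CSV, one row per recorded item (plots without
  items keep a single row with blank item fields);
* habitat patch: GeoJSON Polygon / MultiPolygon in planar metre coordinates;
* assessment output: CSV, one row per plot;
* quality / ANOVA / edge-comparison reports: JSON.

Every output file embeds the run seed and a hash of the run configuration,
so a report can always be traced back to the exact run that produced it.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .permstats import AnovaDesign, perm_anova
from .protocol import (
    AssessmentResult,
    ChecklistItem,
    HabitatProtocol,
    PlotRecord,
    PressureActivity,
    PressureRecord,
    SpeciesObservation,
    TypicalSpecies,
    assess_plot,
)
from .quality import ITEM_KINDS, SurveyDataset, build_incidence, compare_groups, per_plot_richness
from .spatial import as_polygon, compare_edge_distance

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "plot_id",
    "observer_id",
    "observer_status",
    "habitat_code",
    "x",
    "y",
    "area_m2",
    "visit_date",
    "item_kind",
    "item_id",
    "abundance",
    "vitality",
    "intensity",
    "role",
]

__all__ = [
    "read_protocol",
    "write_protocol",
    "read_polygon",
    "write_polygon",
    "read_plot_records",
    "write_plot_records",
    "write_survey",
    "assessment_table",
    "RunConfig",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# protocol YAML

def read_protocol(path: Union[str, Path]) -> HabitatProtocol:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return HabitatProtocol(
            habitat_code=str(raw["habitat_code"]),
            sf_checklist=tuple(
                ChecklistItem(
                    item_id=str(i["id"]),
                    label=str(i.get("label", "")),
                    item_class=str(i.get("class", "natural_feature")),
                )
                for i in raw["sf_checklist"]
            ),
            typical_species=tuple(
                TypicalSpecies(
                    species_id=str(s["id"]),
                    weight=float(s["weight"]),
                    growth_form=str(s.get("growth_form", "woody")),
                )
                for s in raw.get("typical_species", [])
            ),
            pressure_catalogue=tuple(
                PressureActivity(activity_code=str(p["code"]), label=str(p.get("label", "")))
                for p in raw.get("pressure_catalogue", [])
            ),
        )
    except KeyError as exc:
        raise ValueError(f"protocol file {path} is missing key {exc}") from None


def write_protocol(protocol: HabitatProtocol, path: Union[str, Path]) -> None:
    doc = {
        "habitat_code": protocol.habitat_code,
        "sf_checklist": [
            {"id": i.item_id, "label": i.label, "class": i.item_class}
            for i in protocol.sf_checklist
        ],
        "typical_species": [
            {"id": s.species_id, "weight": s.weight, "growth_form": s.growth_form}
            for s in protocol.typical_species
        ],
        "pressure_catalogue": [
            {"code": p.activity_code, "label": p.label} for p in protocol.pressure_catalogue
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# --------------------------------------------------------------------------
# polygon GeoJSON

def read_polygon(path: Union[str, Path]):
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        doc = doc["features"][0]
    if doc.get("type") == "Feature":
        doc = doc["geometry"]
    return as_polygon(shape(doc))


def write_polygon(polygon, path: Union[str, Path]) -> None:
    doc = {
        "type": "Feature",
        "properties": {},
        "geometry": mapping(as_polygon(polygon)),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# --------------------------------------------------------------------------
# plot-records CSV (long format)

def write_plot_records(plots: Sequence[PlotRecord], path: Union[str, Path]) -> None:
    rows: List[dict] = []
    for p in plots:
        base = {
            "plot_id": p.plot_id,
            "observer_id": p.observer_id,
            "observer_status": p.observer_status,
            "habitat_code": p.habitat_code,
            "x": repr(p.location[0]),
            "y": repr(p.location[1]),
            "area_m2": repr(p.area_m2),
            "visit_date": p.visit_date.isoformat() if p.visit_date else "",
        }
        item_rows: List[dict] = []
        for item in sorted(p.structures_present):
            item_rows.append({**base, "item_kind": "structure_function", "item_id": item})
        for obs in p.species_obs:
            item_rows.append(
                {
                    **base,
                    "item_kind": "typical_species",
                    "item_id": obs.species_id,
                    "abundance": obs.abundance,
                    "vitality": obs.vitality,
                }
            )
        for rec in p.pressures:
            item_rows.append(
                {
                    **base,
                    "item_kind": "pressure",
                    "item_id": rec.activity_code,
                    "intensity": rec.intensity,
                    "role": rec.role,
                }
            )
        rows.extend(item_rows if item_rows else [base])
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=RECORD_COLUMNS, restval="")
        writer.writeheader()
        writer.writerows(rows)


def _parse_record_row(row: dict, rownum: int):
    try:
        kind = (row.get("item_kind") or "").strip()
        if kind and kind not in ITEM_KINDS:
            raise ValueError(f"unknown item_kind {kind!r}")
        if kind == "typical_species":
            return kind, SpeciesObservation(
                species_id=row["item_id"],
                abundance=row["abundance"],
                vitality=row["vitality"],
            )
        if kind == "pressure":
            return kind, PressureRecord(
                activity_code=row["item_id"],
                intensity=row["intensity"],
                role=row.get("role") or "pressure",
            )
        if kind == "structure_function":
            if not (row.get("item_id") or "").strip():
                raise ValueError("structure_function row with empty item_id")
            return kind, row["item_id"].strip()
        return None, None  # plot-only row
    except (KeyError, ValueError) as exc:
        raise ValueError(f"row {rownum}: {exc}") from None


def read_plot_records(path: Union[str, Path]) -> List[PlotRecord]:
    """Read and validate a long-format plot-records CSV.

    Malformed rows raise with the offending row number and field; an empty
    file with a valid header returns an empty list with a warning.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        missing = {"plot_id", "observer_id", "observer_status", "habitat_code"} - set(
            reader.fieldnames
        )
        if missing:
            raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
        plots: Dict[str, dict] = {}
        order: List[str] = []
        for rownum, row in enumerate(reader, start=2):
            pid = (row.get("plot_id") or "").strip()
            if not pid:
                raise ValueError(f"row {rownum}: empty plot_id")
            if pid not in plots:
                order.append(pid)
                vd = (row.get("visit_date") or "").strip()
                plots[pid] = {
                    "plot_id": pid,
                    "observer_id": row["observer_id"],
                    "observer_status": row["observer_status"],
                    "habitat_code": row["habitat_code"],
                    "location": (
                        float(row.get("x") or 0.0),
                        float(row.get("y") or 0.0),
                    ),
                    "area_m2": float(row.get("area_m2") or 100.0),
                    "visit_date": date.fromisoformat(vd) if vd else None,
                    "structures": set(),
                    "species": [],
                    "pressures": [],
                }
            kind, value = _parse_record_row(row, rownum)
            if kind == "structure_function":
                plots[pid]["structures"].add(value)
            elif kind == "typical_species":
                plots[pid]["species"].append(value)
            elif kind == "pressure":
                plots[pid]["pressures"].append(value)
    if not plots:
        logger.warning("%s: no plot records found", path)
        return []
    out = []
    for pid in order:
        d = plots[pid]
        out.append(
            PlotRecord(
                plot_id=d["plot_id"],
                habitat_code=d["habitat_code"],
                observer_id=d["observer_id"],
                observer_status=d["observer_status"],
                location=d["location"],
                area_m2=d["area_m2"],
                visit_date=d["visit_date"],
                structures_present=frozenset(d["structures"]),
                species_obs=tuple(d["species"]),
                pressures=tuple(d["pressures"]),
            )
        )
    return out


def write_survey(dataset: SurveyDataset, polygon, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write a survey as the pipeline's three input files (CSV/YAML/GeoJSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "plot_records.csv",
        "protocol": out / "protocol.yaml",
        "polygon": out / "patch.geojson",
    }
    write_plot_records(dataset.plots, paths["records"])
    write_protocol(dataset.protocol, paths["protocol"])
    write_polygon(polygon, paths["polygon"])
    return paths


# --------------------------------------------------------------------------
# assessment output

def assessment_table(dataset: SurveyDataset) -> pd.DataFrame:
    """Assess every plot and return one row per plot."""
    status = {p.plot_id: p.observer_status for p in dataset.plots}
    rows = []
    for plot in dataset.plots:
        r = assess_plot(plot, dataset.protocol)
        rows.append(
            {
                "plot_id": r.plot_id,
                "observer_status": status[r.plot_id],
                "sf_fraction": r.sf_fraction,
                "sf_status": str(r.sf_status),
                "ts_score": r.ts_score,
                "ts_status": str(r.ts_status),
                "pt_status": str(r.pt_status),
                "overall_status": str(r.overall_status),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pipeline

@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    protocol_path: Union[str, Path]
    records_path: Union[str, Path]
    polygon_path: Union[str, Path]
    out_dir: Union[str, Path]
    seed: int
    site_code: str = "SITE1"
    item_kinds: Tuple[str, ...] = ITEM_KINDS
    n_permutations: int = 5000
    min_observers: int = 2
    alternative: str = "two-sided"
    reference_set: Optional[Set[str]] = None

    def digest(self) -> str:
        payload = {
            "protocol_path": str(self.protocol_path),
            "records_path": str(self.records_path),
            "polygon_path": str(self.polygon_path),
            "site_code": self.site_code,
            "item_kinds": list(self.item_kinds),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "min_observers": self.min_observers,
            "alternative": self.alternative,
            "reference_set": sorted(self.reference_set) if self.reference_set else None,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _meta(config: RunConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.digest()}


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Run assessment, quality comparison, permutational ANOVA and the
    edge-distance comparison on one habitat's survey, writing five outputs.

    Outputs: ``assessment.csv``, ``quality.json``, ``anova.json``,
    ``edge_comparison.json`` and ``summary.txt``.  Any stage failure aborts
    with a stage-named error and removes partial outputs.
    """
    for p in (config.protocol_path, config.records_path, config.polygon_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    meta = None
    try:
        stage = "read-inputs"
        protocol = read_protocol(config.protocol_path)
        plots = read_plot_records(config.records_path)
        polygon = read_polygon(config.polygon_path)
        if not plots:
            raise ValueError("no plot records to analyse")
        dataset = SurveyDataset(
            site_code=config.site_code,
            habitat_code=protocol.habitat_code,
            plots=plots,
            protocol=protocol,
        )
        logger.info("read %d plots for habitat %s", len(plots), protocol.habitat_code)
        meta = _meta(config)

        stage = "assessment"
        table = assessment_table(dataset)
        path = out / "assessment.csv"
        with open(path, "w", newline="") as fh:
            fh.write(f"# seed={meta['seed']} config_hash={meta['config_hash']}\n")
            table.to_csv(fh, index=False)
        written.append(path)
        logger.info("assessed %d plots", len(table))

        stage = "quality"
        quality = {
            kind: compare_groups(
                dataset,
                kind,
                reference_set=config.reference_set,
                min_observers=config.min_observers,
            ).to_dict()
            for kind in config.item_kinds
        }
        n_flagged = sum(len(q["flagged_items"]) for q in quality.values())
        logger.info("flagged %d low-support items", n_flagged)
        path = out / "quality.json"
        _write_json({"_meta": meta, **quality}, path)
        written.append(path)

        stage = "anova"
        anova = {}
        for kind in config.item_kinds:
            inc = build_incidence(dataset, kind)
            richness = per_plot_richness(inc)
            pids = sorted(richness)
            design = AnovaDesign(
                response=[richness[pid] for pid in pids],
                factor_status=[inc.observer_status[pid] for pid in pids],
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            anova[kind] = perm_anova(design, factors=("status",)).to_dict()
        path = out / "anova.json"
        _write_json({"_meta": meta, **anova}, path)
        written.append(path)

        stage = "spatial"
        edge = compare_edge_distance(
            dataset,
            polygon,
            n_permutations=config.n_permutations,
            seed=config.seed,
            alternative=config.alternative,
        )
        path = out / "edge_comparison.json"
        _write_json({"_meta": meta, **edge.to_dict()}, path)
        written.append(path)

        stage = "summary"
        path = out / "summary.txt"
        with open(path, "w") as fh:
            fh.write(_summary_text(dataset, table, quality, anova, edge, meta))
        written.append(path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {p.stem: p for p in written}


def _summary_text(dataset, table, quality, anova, edge, meta) -> str:
    lines = [
        f"Habitat {dataset.habitat_code} at site {dataset.site_code}: "
        f"{len(dataset.plots)} plots "
        f"({len(dataset.plots_by_status('expert'))} expert, "
        f"{len(dataset.plots_by_status('non_expert'))} non-expert)",
        f"seed={meta['seed']} config_hash={meta['config_hash']}",
        "",
        "Conservation-status classification per criterion and observer group",
        "-" * 68,
    ]
    for col, label in [
        ("sf_status", "structures & functions"),
        ("ts_status", "typical species"),
        ("pt_status", "future prospects"),
        ("overall_status", "overall"),
    ]:
        lines.append(f"{label}:")
        tally = table.groupby("observer_status")[col].value_counts().unstack(fill_value=0)
        for status_cls in ("FV", "U1", "U2"):
            if status_cls not in tally.columns:
                tally[status_cls] = 0
        tally = tally[["FV", "U1", "U2"]]
        for group, row in tally.iterrows():
            lines.append(
                f"  {group:>10}: FV={row['FV']:>3}  U1={row['U1']:>3}  U2={row['U2']:>3}"
            )
    lines += ["", "Non-expert data quality vs experts", "-" * 68]
    for kind, q in quality.items():
        lines.append(
            f"  {kind}: completeness per-plot {q['completeness_per_plot']:.2f}, "
            f"pooled {q['completeness_pooled']:.2f}; accuracy {q['accuracy']:.2f}; "
            f"{len(q['flagged_items'])} low-support item(s) flagged"
        )
    lines += ["", "Permutational ANOVA on per-plot counts (factor: observer status)", "-" * 68]
    for kind, a in anova.items():
        fr = a["factors"].get("status")
        if fr:
            lines.append(
                f"  {kind}: F = {fr['f_observed']:.2f}, p = {fr['p_value']:.4f} "
                f"({a['n_permutations']} permutations)"
            )
    lines += [
        "",
        "Edge-distance comparison (m)",
        "-" * 68,
        f"  expert mean {edge.mean_dist_expert:.1f}, non-expert mean "
        f"{edge.mean_dist_nonexpert:.1f}, diff {edge.observed_diff:.1f}, "
        f"p = {edge.p_value:.4f} ({edge.alternative})",
        "",
    ]
    return "\n".join(lines)
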