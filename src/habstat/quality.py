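"""Expert vs. non-expert survey comparison.

Quantifies the quality of non-expert (citizen-science) plot records against
expert records for the same habitat type and site, along three axes:

* completeness -- how much of the experts' information the non-experts
  recovered, both per plot (mean per-plot richness ratio) and cumulatively
  (pooled item-set ratio; the "wisdom of the crowds" view);
* accuracy -- the fraction of distinct non-expert-reported items corroborated
  by the pooled expert records or by an optional reference set of items known
  to occur in the region;
* record support -- for each item, how many distinct non-expert observers
  reported it; items below a support threshold (default 2, i.e. records that
  are unique and not repeated by any other observer) are flagged as candidate
  outliers.  Flagging marks, it never deletes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping, Optional, Sequence, Set

import pandas as pd

from .protocol import HabitatProtocol, PlotRecord, _require_unique

logger = logging.getLogger(__name__)

ITEM_KINDS = ("structure_function", "typical_species", "pressure")

__all__ = [
    "ITEM_KINDS",
    "SurveyDataset",
    "IncidenceTable",
    "QualityReport",
    "build_incidence",
    "per_plot_richness",
    "pooled_items",
    "completeness",
    "accuracy",
    "support_counts",
    "flag_low_support",
    "compare_groups",
]


@dataclass
class SurveyDataset:
    """All plots surveyed for one habitat type at one site.

    The unit of the expert vs. non-expert comparison: plots of both observer
    groups for the same habitat, interpreted against one protocol.
    """

    site_code: str
    habitat_code: str
    plots: list
    protocol: HabitatProtocol

    def __post_init__(self):
        if not self.plots:
            raise ValueError("SurveyDataset requires at least one plot")
        _require_unique([p.plot_id for p in self.plots], "plot")
        for p in self.plots:
            if p.habitat_code != self.habitat_code:
                raise ValueError(
                    f"plot {p.plot_id!r} has habitat code {p.habitat_code!r}, "
                    f"dataset is for {self.habitat_code!r}"
                )
        if self.protocol.habitat_code != self.habitat_code:
            raise ValueError(
                f"protocol habitat {self.protocol.habitat_code!r} does not match "
                f"dataset habitat {self.habitat_code!r}"
            )

    def plots_by_status(self, status: str) -> list:
        return [p for p in self.plots if p.observer_status == status]


def _plot_items(plot: PlotRecord, item_kind: str) -> Set[str]:
    if item_kind == "structure_function":
        return set(plot.structures_present)
    if item_kind == "typical_species":
        return {o.species_id for o in plot.species_obs}
    if item_kind == "pressure":
        return {r.activity_code for r in plot.pressures}
    raise ValueError(f"unknown item_kind {item_kind!r}; expected one of {ITEM_KINDS}")


@dataclass
class IncidenceTable:
    """Plot x item 0/1 incidence matrix for one item kind.

    ``matrix`` is indexed by plot_id with one column per item id;
    ``observer_status`` is aligned to the same index.
    """

    item_kind: str
    matrix: pd.DataFrame
    observer_status: pd.Series

    def __post_init__(self):
        if not self.matrix.index.equals(self.observer_status.index):
            raise ValueError("matrix and observer_status must share the same plot index")


def build_incidence(dataset: SurveyDataset, item_kind: str) -> IncidenceTable:
    """Build the incidence table for one item kind.

    Columns are the union of all recorded items; for ``structure_function``
    the full protocol checklist is always included (so that never-recorded
    checklist items appear as all-zero columns).  Columns and rows are sorted
    for deterministic output.
    """
    columns: Set[str] = set()
    if item_kind == "structure_function":
        columns |= set(dataset.protocol.sf_item_ids)
    per_plot = {p.plot_id: _plot_items(p, item_kind) for p in dataset.plots}
    for items in per_plot.values():
        columns |= items
    cols = sorted(columns)
    index = sorted(per_plot)
    matrix = pd.DataFrame(
        [[1 if c in per_plot[pid] else 0 for c in cols] for pid in index],
        index=pd.Index(index, name="plot_id"),
        columns=cols,
        dtype=int,
    )
    status = pd.Series(
        {p.plot_id: p.observer_status for p in dataset.plots}, name="observer_status"
    ).loc[index]
    return IncidenceTable(item_kind=item_kind, matrix=matrix, observer_status=status)


def per_plot_richness(table: IncidenceTable) -> Dict[str, int]:
    """Number of distinct items recorded per plot (row sums)."""
    return {pid: int(v) for pid, v in table.matrix.sum(axis=1).items()}


def pooled_items(table: IncidenceTable, observer_status: str) -> Set[str]:
    """Union of items over all plots of one observer group."""
    mask = table.observer_status == observer_status
    if not mask.any():
        raise ValueError(f"no plots with observer_status {observer_status!r}")
    sub = table.matrix.loc[mask]
    return set(sub.columns[(sub.sum(axis=0) > 0)])


def _group_mean_richness(table: IncidenceTable, status: str) -> float:
    mask = table.observer_status == status
    if not mask.any():
        raise ValueError(f"no plots with observer_status {status!r}")
    return float(table.matrix.loc[mask].sum(axis=1).mean())


def completeness(dataset: SurveyDataset, item_kind: str) -> Dict[str, float]:
    """Non-expert completeness relative to experts, at two levels.

    ``per_plot`` is the ratio of mean non-expert per-plot richness to mean
    expert per-plot richness; ``pooled`` is the ratio of the sizes of the two
    groups' pooled item sets.  Raises when the expert denominator is zero.
    """
    table = build_incidence(dataset, item_kind)
    exp_mean = _group_mean_richness(table, "expert")
    non_mean = _group_mean_richness(table, "non_expert")
    exp_pool = pooled_items(table, "expert")
    non_pool = pooled_items(table, "non_expert")
    if exp_mean == 0:
        raise ValueError("expert mean per-plot richness is 0; per-plot ratio undefined")
    if not exp_pool:
        raise ValueError("expert pooled item set is empty; pooled ratio undefined")
    return {"per_plot": non_mean / exp_mean, "pooled": len(non_pool) / len(exp_pool)}


def accuracy(
    dataset: SurveyDataset,
    item_kind: str,
    reference_set: Optional[Set[str]] = None,
) -> float:
    """Fraction of distinct non-expert items corroborated by experts.

    An item counts as corroborated if it appears in the experts' pooled
    records or in ``reference_set`` (items independently known to occur in
    the region).  Defined over distinct items, not record instances.
    """
    table = build_incidence(dataset, item_kind)
    non_pool = pooled_items(table, "non_expert")
    if not non_pool:
        raise ValueError("accuracy undefined: non-experts reported no items")
    corroborated = pooled_items(table, "expert") | (reference_set or set())
    return len(non_pool & corroborated) / len(non_pool)


def support_counts(dataset: SurveyDataset, item_kind: str) -> Dict[str, int]:
    """Distinct non-expert observers reporting each item.

    Counts observers, not plots: an item reported twice by the same observer
    has support 1.  Items never reported by a non-expert do not appear.
    """
    observers: Dict[str, Set[str]] = {}
    for plot in dataset.plots_by_status("non_expert"):
        for item in _plot_items(plot, item_kind):
            observers.setdefault(item, set()).add(plot.observer_id)
    return {item: len(obs) for item, obs in observers.items()}


def flag_low_support(support: Mapping[str, int], min_observers: int = 2) -> Set[str]:
    """Items whose support falls below ``min_observers``.

    With the default threshold of 2, exactly the records that are unique and
    not repeated by any other observer are flagged.  Flagging only marks
    items; removing or downweighting them is a separate, explicit step.
    """
    if min_observers < 1:
        raise ValueError(f"min_observers must be >= 1, got {min_observers}")
    return {item for item, n in support.items() if n < min_observers}


@dataclass
class QualityReport:
    """Assembled expert vs. non-expert comparison for one item kind."""

    item_kind: str
    per_plot_means: Dict[str, float]
    completeness_per_plot: float
    completeness_pooled: float
    accuracy: float
    items_only_experts: FrozenSet[str]
    items_only_nonexperts: FrozenSet[str]
    items_shared: FrozenSet[str]
    support_counts: Dict[str, int]
    flagged_items: FrozenSet[str]
    min_observers: int

    def to_dict(self) -> dict:
        return {
            "item_kind": self.item_kind,
            "per_plot_means": dict(self.per_plot_means),
            "completeness_per_plot": self.completeness_per_plot,
            "completeness_pooled": self.completeness_pooled,
            "accuracy": self.accuracy,
            "items_only_experts": sorted(self.items_only_experts),
            "items_only_nonexperts": sorted(self.items_only_nonexperts),
            "items_shared": sorted(self.items_shared),
            "support_counts": dict(sorted(self.support_counts.items())),
            "flagged_items": sorted(self.flagged_items),
            "min_observers": self.min_observers,
        }


def compare_groups(
    dataset: SurveyDataset,
    item_kind: str = "structure_function",
    reference_set: Optional[Set[str]] = None,
    min_observers: int = 2,
) -> QualityReport:
    """Full expert vs. non-expert comparison for one item kind.

    Combines per-plot means, completeness ratios, accuracy, the partition of
    pooled items into shared / expert-only / non-expert-only, and
    low-support flagging of non-expert records.
    """
    table = build_incidence(dataset, item_kind)
    exp_pool = pooled_items(table, "expert")
    non_pool = pooled_items(table, "non_expert")
    comp = completeness(dataset, item_kind)
    support = support_counts(dataset, item_kind)
    return QualityReport(
        item_kind=item_kind,
        per_plot_means={
            "expert": _group_mean_richness(table, "expert"),
            "non_expert": _group_mean_richness(table, "non_expert"),
        },
        completeness_per_plot=comp["per_plot"],
        completeness_pooled=comp["pooled"],
        accuracy=accuracy(dataset, item_kind, reference_set),
        items_only_experts=frozenset(exp_pool - non_pool),
        items_only_nonexperts=frozenset(non_pool - exp_pool),
        items_shared=frozenset(exp_pool & non_pool),
        support_counts=support,
        flagged_items=frozenset(flag_low_support(support, min_observers)),
        min_observers=min_observers,
    )
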