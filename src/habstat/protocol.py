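"""Plot-level conservation-status classification for Annex I habitat types.

National Article 17 monitoring assesses each 100 m2 sample plot against three
criteria: (i) specific structures and functions -- a habitat-specific checklist
of indicators of ecosystem health, scored by the fraction of items present;
(ii) typical species -- a weighted list of species representative of the
habitat's plant community, recorded with abundance and vitality classes; and
(iii) pressures and threats -- human or natural activities recorded with an
intensity class, which determine the habitat's future prospects.  Each
criterion maps to one of three ordered conservation-status classes:

* ``FV``  Favourable
* ``U1``  Unfavourable - Inadequate
* ``U2``  Unfavourable - Bad

The classification rules implemented here are deterministic threshold rules:

* structures & functions: FV if strictly more than 50 % of the checklist is
  present, U1 for the closed interval 25-50 %, U2 below 25 %;
* future prospects: FV with no pressures/threats (or a single one of low or
  medium intensity), U1 with two or three records all of low/medium
  intensity, U2 with any high-intensity record or more than three records;
* typical species: a weighted score in [0, 1] (see
  :func:`score_typical_species`), classified with the same 50 %/25 %
  thresholds as the structures & functions criterion.

The per-plot overall status is the worst ("one-out-all-out") of the three
criterion statuses, the standard convention for combining Article 17 criteria.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

__all__ = [
    "StatusClass",
    "ChecklistItem",
    "TypicalSpecies",
    "PressureActivity",
    "HabitatProtocol",
    "SpeciesObservation",
    "PressureRecord",
    "PlotRecord",
    "AssessmentResult",
    "ABUNDANCE_LEVELS",
    "VITALITY_LEVELS",
    "INTENSITY_LEVELS",
    "ABUNDANCE_MULTIPLIER",
    "VITALITY_MULTIPLIER",
    "classify_structures_functions",
    "classify_future_prospects",
    "score_typical_species",
    "classify_typical_species",
    "assess_plot",
]


class StatusClass(enum.IntEnum):
    """Ordered conservation-status class; the integer value orders 'badness'."""

    FV = 0
    U1 = 1
    U2 = 2

    def __str__(self) -> str:  # canonical short code
        return self.name

    @classmethod
    def from_string(cls, value: str) -> "StatusClass":
        try:
            return cls[value.strip().upper()]
        except KeyError:
            raise ValueError(
                f"invalid status class {value!r}; expected one of FV, U1, U2"
            ) from None

    @classmethod
    def worst(cls, statuses: Iterable["StatusClass"]) -> "StatusClass":
        """Worst (highest-badness) status of a non-empty collection."""
        statuses = list(statuses)
        if not statuses:
            raise ValueError("worst() requires at least one status")
        return max(statuses)


# Ordered categorical levels, worst-to-best for abundance/vitality.
ABUNDANCE_LEVELS: Tuple[str, ...] = ("rare", "occasional", "frequent", "abundant")
VITALITY_LEVELS: Tuple[str, ...] = ("poor", "moderate", "good")
INTENSITY_LEVELS: Tuple[str, ...] = ("low", "medium", "high")
PRESSURE_ROLES: Tuple[str, ...] = ("pressure", "threat", "both")
OBSERVER_STATUSES: Tuple[str, ...] = ("expert", "non_expert")
SF_ITEM_CLASSES: Tuple[str, ...] = ("natural_feature", "degradation_absence")
GROWTH_FORMS: Tuple[str, ...] = ("woody", "herbaceous")

# Fixed ordinal multipliers of the typical-species score (see score_typical_species).
ABUNDANCE_MULTIPLIER = {"rare": 0.25, "occasional": 0.5, "frequent": 0.75, "abundant": 1.0}
VITALITY_MULTIPLIER = {"poor": 0.5, "moderate": 0.75, "good": 1.0}


def _canon(value: str, allowed: Sequence[str], field_name: str) -> str:
    """Normalise a categorical value: case-insensitive in, lower-case out."""
    v = str(value).strip().lower()
    if v not in allowed:
        raise ValueError(
            f"invalid {field_name} {value!r}; expected one of {', '.join(allowed)}"
        )
    return v


@dataclass(frozen=True)
class ChecklistItem:
    """One structures-and-functions checklist entry (true/false in the field)."""

    item_id: str
    label: str = ""
    item_class: str = "natural_feature"

    def __post_init__(self):
        object.__setattr__(
            self, "item_class", _canon(self.item_class, SF_ITEM_CLASSES, "item_class")
        )


@dataclass(frozen=True)
class TypicalSpecies:
    """A typical species with its representativity weight.

    ``growth_form`` distinguishes woody from herbaceous species; it does not
    enter the score but drives detectability in the survey simulator.
    """

    species_id: str
    weight: float
    growth_form: str = "woody"

    def __post_init__(self):
        if not self.weight > 0:
            raise ValueError(f"weight for {self.species_id!r} must be > 0, got {self.weight}")
        object.__setattr__(
            self, "growth_form", _canon(self.growth_form, GROWTH_FORMS, "growth_form")
        )


@dataclass(frozen=True)
class PressureActivity:
    """Catalogue entry for a pressure/threat activity (EEA reference list style)."""

    activity_code: str
    label: str = ""


def _require_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class HabitatProtocol:
    """The per-habitat assessment template.

    Holds the structures-and-functions checklist, the weighted typical-species
    list and the pressure catalogue for one habitat type (e.g. ``"2120"``).
    """

    habitat_code: str
    sf_checklist: Tuple[ChecklistItem, ...]
    typical_species: Tuple[TypicalSpecies, ...] = ()
    pressure_catalogue: Tuple[PressureActivity, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "sf_checklist", tuple(self.sf_checklist))
        object.__setattr__(self, "typical_species", tuple(self.typical_species))
        object.__setattr__(self, "pressure_catalogue", tuple(self.pressure_catalogue))
        if not self.sf_checklist:
            raise ValueError("sf_checklist must be non-empty")
        _require_unique([i.item_id for i in self.sf_checklist], "checklist item")
        _require_unique([s.species_id for s in self.typical_species], "typical species")
        _require_unique([p.activity_code for p in self.pressure_catalogue], "pressure activity")

    @property
    def sf_item_ids(self) -> frozenset:
        return frozenset(i.item_id for i in self.sf_checklist)

    @property
    def species_ids(self) -> frozenset:
        return frozenset(s.species_id for s in self.typical_species)

    @property
    def pressure_codes(self) -> frozenset:
        return frozenset(p.activity_code for p in self.pressure_catalogue)

    @property
    def species_weights(self) -> dict:
        return {s.species_id: s.weight for s in self.typical_species}


@dataclass(frozen=True)
class SpeciesObservation:
    """One typical-species record: abundance and vitality classes."""

    species_id: str
    abundance: str
    vitality: str

    def __post_init__(self):
        object.__setattr__(
            self, "abundance", _canon(self.abundance, ABUNDANCE_LEVELS, "abundance")
        )
        object.__setattr__(
            self, "vitality", _canon(self.vitality, VITALITY_LEVELS, "vitality")
        )


@dataclass(frozen=True)
class PressureRecord:
    """One pressure/threat record with intensity and role.

    An activity already acting that will continue in the foreseeable future is
    both a pressure and a threat (``role="both"``); for the future-prospects
    rule each record counts once regardless of role.
    """

    activity_code: str
    intensity: str
    role: str = "pressure"

    def __post_init__(self):
        object.__setattr__(
            self, "intensity", _canon(self.intensity, INTENSITY_LEVELS, "intensity")
        )
        object.__setattr__(self, "role", _canon(self.role, PRESSURE_ROLES, "role"))


@dataclass(frozen=True)
class PlotRecord:
    """One completed field protocol: who observed what, where."""

    plot_id: str
    habitat_code: str
    observer_id: str
    observer_status: str
    location: Tuple[float, float] = (0.0, 0.0)
    area_m2: float = 100.0
    visit_date: Optional[date] = None
    structures_present: frozenset = frozenset()
    species_obs: Tuple[SpeciesObservation, ...] = ()
    pressures: Tuple[PressureRecord, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self,
            "observer_status",
            _canon(self.observer_status, OBSERVER_STATUSES, "observer_status"),
        )
        object.__setattr__(self, "structures_present", frozenset(self.structures_present))
        object.__setattr__(self, "species_obs", tuple(self.species_obs))
        object.__setattr__(self, "pressures", tuple(self.pressures))
        object.__setattr__(
            self, "location", (float(self.location[0]), float(self.location[1]))
        )
        if not self.area_m2 > 0:
            raise ValueError(f"area_m2 must be > 0, got {self.area_m2}")
        _require_unique([o.species_id for o in self.species_obs], "species observation")


@dataclass(frozen=True)
class AssessmentResult:
    """Per-plot criterion scores and FV/U1/U2 classes."""

    plot_id: str
    sf_fraction: float
    sf_status: StatusClass
    ts_score: float
    ts_status: StatusClass
    pt_status: StatusClass
    overall_status: StatusClass


def _classify_fraction(fraction: float) -> StatusClass:
    """Shared 50 %/25 % threshold rule.

    FV requires strictly more than half; the middle band is the closed
    interval [0.25, 0.5]; U2 requires strictly less than a quarter.
    """
    if fraction > 0.5:
        return StatusClass.FV
    if fraction >= 0.25:
        return StatusClass.U1
    return StatusClass.U2


def classify_structures_functions(n_present: int, checklist_size: int) -> StatusClass:
    """Classify the structures-and-functions criterion from item counts.

    Parameters
    ----------
    n_present
        Number of checklist items recorded present in the plot.
    checklist_size
        Total number of items on the habitat's checklist (>= 1).

    Returns
    -------
    StatusClass
        FV if more than 50 % of items are present, U1 for 25-50 %
        (closed interval), U2 below 25 %.
    """
    if checklist_size < 1:
        raise ValueError(f"checklist_size must be >= 1, got {checklist_size}")
    if n_present < 0:
        raise ValueError(f"n_present must be >= 0, got {n_present}")
    if n_present > checklist_size:
        raise ValueError(
            f"n_present ({n_present}) exceeds checklist_size ({checklist_size})"
        )
    return _classify_fraction(n_present / checklist_size)


def classify_future_prospects(pressures: Sequence[PressureRecord]) -> StatusClass:
    """Classify future prospects from the pressure/threat records of a plot.

    FV: no records, or exactly one of low/medium intensity.  U2: any record of
    high intensity, or more than three records.  U1: everything in between
    (two or three records, all of low/medium intensity).  Each record counts
    once, whether it is a pressure, a threat or both.
    """
    records = list(pressures)
    n = len(records)
    any_high = any(r.intensity == "high" for r in records)
    if any_high or n > 3:
        return StatusClass.U2
    if n <= 1:
        return StatusClass.FV
    return StatusClass.U1


def score_typical_species(
    species_obs: Sequence[SpeciesObservation], protocol: HabitatProtocol
) -> float:
    """Weighted typical-species score in [0, 1].

    score = sum over observed typical species of
    ``weight * a(abundance) * v(vitality)``, normalised by the total weight of
    the protocol's typical-species list, with ordinal multipliers
    a(rare)=0.25, a(occasional)=0.5, a(frequent)=0.75, a(abundant)=1.0 and
    v(poor)=0.5, v(moderate)=0.75, v(good)=1.0.  The score is 1 exactly when
    every typical species is observed as abundant with good vitality, and
    increases monotonically in every abundance or vitality class.

    Species ids not on the protocol list (e.g. off-list species recorded by
    non-experts) are ignored with a logged warning.
    """
    if not protocol.typical_species:
        raise ValueError(
            f"protocol {protocol.habitat_code!r} has an empty typical-species list"
        )
    weights = protocol.species_weights
    total = sum(weights.values())
    score = 0.0
    for obs in species_obs:
        w = weights.get(obs.species_id)
        if w is None:
            logger.warning(
                "species %r not on the typical-species list of habitat %s; ignored",
                obs.species_id,
                protocol.habitat_code,
            )
            continue
        score += w * ABUNDANCE_MULTIPLIER[obs.abundance] * VITALITY_MULTIPLIER[obs.vitality]
    return score / total


def classify_typical_species(ts_score: float) -> StatusClass:
    """Classify the typical-species score with the shared 50 %/25 % thresholds."""
    if not 0.0 <= ts_score <= 1.0:
        raise ValueError(f"ts_score must lie in [0, 1], got {ts_score}")
    return _classify_fraction(ts_score)


def assess_plot(plot: PlotRecord, protocol: HabitatProtocol) -> AssessmentResult:
    """Run all three criterion classifiers on one plot.

    The overall status is the worst of the three criterion statuses
    (one-out-all-out).  Raises if the plot's habitat code does not match the
    protocol's, or if the plot records checklist items unknown to the
    protocol.
    """
    if plot.habitat_code != protocol.habitat_code:
        raise ValueError(
            f"plot {plot.plot_id!r} has habitat code {plot.habitat_code!r} but the "
            f"protocol is for habitat {protocol.habitat_code!r}"
        )
    unknown = plot.structures_present - protocol.sf_item_ids
    if unknown:
        raise ValueError(
            f"plot {plot.plot_id!r} records checklist items not in the protocol: "
            f"{sorted(unknown)}"
        )
    size = len(protocol.sf_checklist)
    n_present = len(plot.structures_present)
    sf_fraction = n_present / size
    sf_status = classify_structures_functions(n_present, size)
    ts_score = score_typical_species(plot.species_obs, protocol)
    ts_status = classify_typical_species(ts_score)
    pt_status = classify_future_prospects(plot.pressures)
    return AssessmentResult(
        plot_id=plot.plot_id,
        sf_fraction=sf_fraction,
        sf_status=sf_status,
        ts_score=ts_score,
        ts_status=ts_status,
        pt_status=pt_status,
        overall_status=StatusClass.worst([sf_status, ts_status, pt_status]),
    )
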