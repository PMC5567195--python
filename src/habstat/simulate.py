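"""Synthetic observer-survey generator.

Generates plot-protocol surveys with the statistical structure the analysis
assumes, so every pipeline stage is testable without field data:

* a latent habitat-condition gradient: the probability that "good" checklist
  items and typical species are truly present rises with distance from the
  patch edge (logistic in distance), while pressures are more numerous and
  more intense near the edge -- the edge is the marginal, degraded zone;
* two observer classes with unequal per-item detection probability; woody
  species are detected more reliably than herbaceous ones, whose
  detectability can be further reduced by a seasonal factor (herbs dormant in
  late autumn);
* rare non-expert false positives (an absent item recorded anyway), which
  receive the lowest abundance/vitality classes;
* edge-biased non-expert plot placement: proposals uniform in the patch are
  accepted with probability exp(-d/lambda) where d is the distance to the
  edge, so a small lambda concentrates plots near the boundary.  Experts
  place plots uniformly (lambda = None, i.e. infinite).

The default configuration mirrors the study design: a handful of expert
plots (each expert surveys several) against tens of non-expert plots (one
plot per volunteer), 100 m2 plots, a 10-item checklist.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Point, Polygon, box

from .protocol import (
    ChecklistItem,
    HabitatProtocol,
    PlotRecord,
    PressureActivity,
    PressureRecord,
    SpeciesObservation,
    TypicalSpecies,
    ABUNDANCE_LEVELS,
    VITALITY_LEVELS,
    INTENSITY_LEVELS,
)
from .quality import SurveyDataset
from .spatial import as_polygon, distances_to_edge

logger = logging.getLogger(__name__)

RngLike = Union[int, np.random.Generator]

# detection-probability item classes
ITEM_CLASSES = ("woody_species", "herbaceous_species", "structure", "pressure")

__all__ = [
    "ObserverModel",
    "GradientParams",
    "LatentPlotTruth",
    "SimulationConfig",
    "expert_observer",
    "nonexpert_observer",
    "generate_protocol",
    "sample_plot_locations",
    "generate_truth",
    "simulate_observation",
    "simulate_survey",
]


def _rng(seed_or_rng: RngLike) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class ObserverModel:
    """The latent detection and placement process one observer class follows.

    ``detect_prob`` maps item class (woody_species, herbaceous_species,
    structure, pressure) to the per-item detection probability.
    ``season_factor`` multiplies herbaceous detectability (1 = growing
    season, small values = herbs dormant).  ``false_positive_rate`` is the
    per-absent-item probability of a spurious record.
    ``edge_scale_lambda`` (metres) controls plot placement: acceptance
    probability exp(-d/lambda); ``None`` means uniform placement.
    """

    status: str
    detect_prob: Dict[str, float]
    season_factor: float = 1.0
    false_positive_rate: float = 0.0
    edge_scale_lambda: Optional[float] = None

    def __post_init__(self):
        for cls in ITEM_CLASSES:
            p = self.detect_prob.get(cls)
            if p is None or not 0.0 <= p <= 1.0:
                raise ValueError(f"detect_prob[{cls!r}] must be in [0, 1], got {p}")
        if not 0.0 <= self.season_factor <= 1.0:
            raise ValueError("season_factor must be in [0, 1]")
        if not 0.0 <= self.false_positive_rate <= 1.0:
            raise ValueError("false_positive_rate must be in [0, 1]")
        if self.edge_scale_lambda is not None and not self.edge_scale_lambda > 0:
            raise ValueError("edge_scale_lambda must be > 0 (or None for uniform)")

    def effective_detect_prob(self, item_class: str) -> float:
        p = self.detect_prob[item_class]
        if item_class == "herbaceous_species":
            p *= self.season_factor
        return p


def expert_observer(**overrides) -> ObserverModel:
    """Default expert: 0.9 detection everywhere, no false positives, uniform placement."""
    base = ObserverModel(
        status="expert",
        detect_prob={c: 0.9 for c in ITEM_CLASSES},
        season_factor=1.0,
        false_positive_rate=0.0,
        edge_scale_lambda=None,
    )
    return replace(base, **overrides) if overrides else base


def nonexpert_observer(**overrides) -> ObserverModel:
    """Default non-expert: lower, class-dependent detection, rare false
    positives, edge-biased placement (lambda = 5 m)."""
    base = ObserverModel(
        status="non_expert",
        detect_prob={
            "woody_species": 0.85,
            "herbaceous_species": 0.35,
            "structure": 0.6,
            "pressure": 0.5,
        },
        season_factor=1.0,
        false_positive_rate=0.01,
        edge_scale_lambda=5.0,
    )
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class GradientParams:
    """Edge-to-core habitat-condition gradient.

    The probability that a good item (checklist indicator or typical species)
    is truly present at distance d from the edge is logistic(alpha + beta*d).
    The expected pressure count is ``pressure_mean_edge * exp(-d/
    pressure_dist_scale)`` (truncated at the catalogue size), and recorded
    intensities interpolate between an edge distribution (mostly high) and a
    core distribution (mostly low) with the same exponential weight.
    """

    alpha: float = -0.2
    beta: float = 0.08
    pressure_mean_edge: float = 3.0
    pressure_dist_scale: float = 15.0
    intensity_probs_edge: Tuple[float, float, float] = (0.2, 0.3, 0.5)  # low, med, high
    intensity_probs_core: Tuple[float, float, float] = (0.6, 0.3, 0.1)

    def presence_prob(self, d: float) -> float:
        return 1.0 / (1.0 + math.exp(-(self.alpha + self.beta * d)))

    def pressure_mean(self, d: float) -> float:
        return self.pressure_mean_edge * math.exp(-d / self.pressure_dist_scale)

    def intensity_probs(self, d: float) -> np.ndarray:
        w = math.exp(-d / self.pressure_dist_scale)
        edge = np.asarray(self.intensity_probs_edge, dtype=float)
        core = np.asarray(self.intensity_probs_core, dtype=float)
        p = w * edge + (1 - w) * core
        return p / p.sum()


@dataclass(frozen=True)
class LatentPlotTruth:
    """What is actually on the ground at one plot location."""

    location: Tuple[float, float]
    distance_to_edge: float
    structures_true: frozenset
    species_true: Dict[str, SpeciesObservation]
    pressures_true: Tuple[PressureRecord, ...]

    @property
    def items_true(self) -> frozenset:
        return (
            frozenset(self.structures_true)
            | frozenset(self.species_true)
            | frozenset(r.activity_code for r in self.pressures_true)
        )


@dataclass
class SimulationConfig:
    """Full specification of one synthetic survey.

    Defaults follow the study design: 6 expert plots shared by 2 experts
    against 30 non-expert plots (one volunteer each), a 10-item checklist,
    8 typical species (half woody), 6 pressure codes, a 100 m square patch.
    ``n_absent_species`` additional species are appended to the typical list
    but never truly occur at the site -- typical-species lists are compiled
    regionally, so they routinely carry species missing from a given site;
    records of these can only be false positives.
    """

    seed: int
    site_code: str = "SITE1"
    habitat_code: str = "2120"
    n_structure_items: int = 10
    n_typical_species: int = 8
    prop_woody: float = 0.5
    n_absent_species: int = 2  # on the typical list but locally absent
    n_pressure_codes: int = 6
    polygon: Union[Polygon, MultiPolygon, dict, None] = None  # default: 100 m square
    n_experts: int = 2
    n_expert_plots: int = 6
    n_nonexpert_plots: int = 30
    expert_model: ObserverModel = field(default_factory=expert_observer)
    nonexpert_model: ObserverModel = field(default_factory=nonexpert_observer)
    gradient: GradientParams = field(default_factory=GradientParams)

    def __post_init__(self):
        for name in (
            "n_structure_items",
            "n_typical_species",
            "n_pressure_codes",
            "n_experts",
            "n_expert_plots",
            "n_nonexpert_plots",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.prop_woody <= 1.0:
            raise ValueError("prop_woody must be in [0, 1]")

    def patch(self) -> Union[Polygon, MultiPolygon]:
        if self.polygon is None:
            return box(0.0, 0.0, 100.0, 100.0)
        return as_polygon(self.polygon)

    def absent_species_ids(self) -> frozenset:
        """Ids of the typical-list species that never occur at the site."""
        n_total = self.n_typical_species + self.n_absent_species
        return frozenset(
            f"sp{i + 1:02d}" for i in range(self.n_typical_species, n_total)
        )


def generate_protocol(config: SimulationConfig, seed: Optional[RngLike] = None) -> HabitatProtocol:
    """Generate a synthetic habitat protocol with the configured cardinalities.

    Checklist item classes alternate natural-feature / degradation-absence;
    the first ``round(prop_woody * n)`` species are woody, the rest
    herbaceous; weights are drawn uniformly from {1, 2, 3}.  The
    ``n_absent_species`` locally-absent species are appended last (as
    herbaceous -- the easily confused growth form).
    """
    rng = _rng(config.seed if seed is None else seed)
    sf = tuple(
        ChecklistItem(
            item_id=f"sf{i + 1:02d}",
            label=f"structure/function indicator {i + 1}",
            item_class="natural_feature" if i % 2 == 0 else "degradation_absence",
        )
        for i in range(config.n_structure_items)
    )
    n_woody = round(config.prop_woody * config.n_typical_species)
    n_total_species = config.n_typical_species + config.n_absent_species
    weights = rng.integers(1, 4, size=n_total_species)
    species = tuple(
        TypicalSpecies(
            species_id=f"sp{i + 1:02d}",
            weight=int(weights[i]),
            growth_form="woody" if i < n_woody else "herbaceous",
        )
        for i in range(n_total_species)
    )
    pressures = tuple(
        PressureActivity(activity_code=f"A{i + 1:02d}", label=f"activity {i + 1}")
        for i in range(config.n_pressure_codes)
    )
    return HabitatProtocol(
        habitat_code=config.habitat_code,
        sf_checklist=sf,
        typical_species=species,
        pressure_catalogue=pressures,
    )


def sample_plot_locations(
    polygon: Union[Polygon, MultiPolygon, dict],
    observer: ObserverModel,
    n: int,
    seed: RngLike,
    max_proposals: int = 1_000_000,
) -> np.ndarray:
    """Sample n plot locations inside the patch, edge-biased per the observer.

    Rejection sampling: propose uniformly in the patch, accept with
    probability exp(-d/lambda) where d is the distance to the boundary (the
    maximal acceptance probability is 1, at the edge itself, so no further
    normalisation is needed).  Uniform placement when lambda is None.
    Returns an (n, 2) array; deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    poly = as_polygon(polygon)
    rng = _rng(seed)
    minx, miny, maxx, maxy = poly.bounds
    lam = observer.edge_scale_lambda
    accepted: List[np.ndarray] = []
    n_acc = 0
    proposed = 0
    batch = max(4 * n, 256)
    while n_acc < n:
        if proposed > max_proposals:
            raise RuntimeError(
                f"plot placement stalled after {proposed} proposals; "
                "edge_scale_lambda is likely too small for this patch"
            )
        xy = np.column_stack(
            [rng.uniform(minx, maxx, batch), rng.uniform(miny, maxy, batch)]
        )
        proposed += batch
        pts = shapely.points(xy)
        inside = shapely.covers(poly, pts)
        xy = xy[inside]
        if xy.size == 0:
            continue
        if lam is not None:
            d = shapely.distance(poly.boundary, shapely.points(xy))
            keep = rng.uniform(size=len(xy)) < np.exp(-d / lam)
            xy = xy[keep]
        if len(xy):
            accepted.append(xy)
            n_acc += len(xy)
    return np.concatenate(accepted)[:n]


def generate_truth(
    location: Tuple[float, float],
    protocol: HabitatProtocol,
    gradient: GradientParams,
    polygon: Union[Polygon, MultiPolygon, dict],
    seed: RngLike,
    absent_items: frozenset = frozenset(),
) -> LatentPlotTruth:
    """Draw the latent ground truth at one location from the condition gradient.

    Items listed in ``absent_items`` are never present (typical-list species
    that do not occur at this site).  Each other checklist item and typical
    species is truly present independently
    with probability logistic(alpha + beta*d); abundance and vitality of
    present species are drawn from binomial ordinal models with the same
    success probability, so species are more abundant and more vital in the
    core.  Pressure count is Poisson with mean decreasing in d (truncated at
    the catalogue size), with distinct activity codes and intensities drawn
    from the distance-interpolated categorical distribution.
    """
    rng = _rng(seed)
    poly = as_polygon(polygon)
    d = float(distances_to_edge(np.asarray([location], dtype=float), poly)[0])
    p_good = gradient.presence_prob(d)

    structures = frozenset(
        item.item_id
        for item in protocol.sf_checklist
        if item.item_id not in absent_items and rng.uniform() < p_good
    )
    species: Dict[str, SpeciesObservation] = {}
    for sp in protocol.typical_species:
        if sp.species_id not in absent_items and rng.uniform() < p_good:
            abundance = ABUNDANCE_LEVELS[rng.binomial(len(ABUNDANCE_LEVELS) - 1, p_good)]
            vitality = VITALITY_LEVELS[rng.binomial(len(VITALITY_LEVELS) - 1, p_good)]
            species[sp.species_id] = SpeciesObservation(sp.species_id, abundance, vitality)

    n_codes = len(protocol.pressure_catalogue)
    n_pressures = min(int(rng.poisson(gradient.pressure_mean(d))), n_codes)
    pressures: Tuple[PressureRecord, ...] = ()
    if n_pressures > 0 and n_codes > 0:
        codes = sorted(protocol.pressure_codes)
        chosen = rng.choice(len(codes), size=n_pressures, replace=False)
        probs = gradient.intensity_probs(d)
        pressures = tuple(
            PressureRecord(
                activity_code=codes[i],
                intensity=INTENSITY_LEVELS[rng.choice(3, p=probs)],
                role="both",
            )
            for i in sorted(chosen)
        )
    return LatentPlotTruth(
        location=(float(location[0]), float(location[1])),
        distance_to_edge=d,
        structures_true=structures,
        species_true=species,
        pressures_true=pressures,
    )


def simulate_observation(
    truth: LatentPlotTruth,
    observer: ObserverModel,
    plot_id: str,
    seed: RngLike,
    protocol: HabitatProtocol,
    observer_id: str = "obs",
) -> PlotRecord:
    """One observer's (imperfect) record of a plot.

    Every true item is recorded with the observer's class-specific detection
    probability; every absent catalogue item is recorded with the
    false-positive rate.  Detected species copy abundance/vitality from the
    truth; false-positive species are recorded at the lowest classes
    (abundance rare, vitality poor) -- a spurious record is never an
    abundant, vigorous population.  False-positive pressures get low
    intensity.
    """
    rng = _rng(seed)
    growth_form = {s.species_id: s.growth_form for s in protocol.typical_species}

    structures = set()
    p_struct = observer.effective_detect_prob("structure")
    for item in protocol.sf_checklist:
        if item.item_id in truth.structures_true:
            if rng.uniform() < p_struct:
                structures.add(item.item_id)
        elif rng.uniform() < observer.false_positive_rate:
            structures.add(item.item_id)

    species_obs: List[SpeciesObservation] = []
    for sp in protocol.typical_species:
        cls = f"{growth_form[sp.species_id]}_species"
        if sp.species_id in truth.species_true:
            if rng.uniform() < observer.effective_detect_prob(cls):
                species_obs.append(truth.species_true[sp.species_id])
        elif rng.uniform() < observer.false_positive_rate:
            species_obs.append(SpeciesObservation(sp.species_id, "rare", "poor"))

    pressures: List[PressureRecord] = []
    true_codes = {r.activity_code: r for r in truth.pressures_true}
    p_press = observer.effective_detect_prob("pressure")
    for entry in protocol.pressure_catalogue:
        rec = true_codes.get(entry.activity_code)
        if rec is not None:
            if rng.uniform() < p_press:
                pressures.append(rec)
        elif rng.uniform() < observer.false_positive_rate:
            pressures.append(PressureRecord(entry.activity_code, "low", "pressure"))

    return PlotRecord(
        plot_id=plot_id,
        habitat_code=protocol.habitat_code,
        observer_id=observer_id,
        observer_status=observer.status,
        location=truth.location,
        structures_present=frozenset(structures),
        species_obs=tuple(species_obs),
        pressures=tuple(pressures),
    )


def simulate_survey(
    config: SimulationConfig, return_truth: bool = False
) -> Union[SurveyDataset, Tuple[SurveyDataset, Dict[str, LatentPlotTruth]]]:
    """Simulate a full survey of one habitat type at one site.

    Expert plots are shared round-robin among the expert observers (each
    expert surveys several plots); each non-expert plot has its own observer.
    Fully deterministic given ``config.seed``.  With ``return_truth=True``
    also returns the latent truth of every plot, keyed by plot id.
    """
    rng = np.random.default_rng(config.seed)
    protocol = generate_protocol(config, rng)
    poly = config.patch()
    absent = config.absent_species_ids()

    exp_xy = sample_plot_locations(poly, config.expert_model, config.n_expert_plots, rng)
    non_xy = sample_plot_locations(
        poly, config.nonexpert_model, config.n_nonexpert_plots, rng
    )

    plots: List[PlotRecord] = []
    truths: Dict[str, LatentPlotTruth] = {}
    for i, xy in enumerate(exp_xy):
        pid = f"E{i + 1:03d}"
        truth = generate_truth(
            tuple(xy), protocol, config.gradient, poly, rng, absent_items=absent
        )
        truths[pid] = truth
        plots.append(
            simulate_observation(
                truth,
                config.expert_model,
                pid,
                rng,
                protocol,
                observer_id=f"expert_{i % config.n_experts + 1:02d}",
            )
        )
    for i, xy in enumerate(non_xy):
        pid = f"N{i + 1:03d}"
        truth = generate_truth(
            tuple(xy), protocol, config.gradient, poly, rng, absent_items=absent
        )
        truths[pid] = truth
        plots.append(
            simulate_observation(
                truth,
                config.nonexpert_model,
                pid,
                rng,
                protocol,
                observer_id=f"vol_{i + 1:03d}",
            )
        )
    dataset = SurveyDataset(
        site_code=config.site_code,
        habitat_code=config.habitat_code,
        plots=plots,
        protocol=protocol,
    )
    return (dataset, truths) if return_truth else dataset
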