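"""Synthetic survey generator: determinism, detection thinning, placement bias."""

import numpy as np
import pytest
import shapely
from shapely.geometry import box

from habstat.protocol import SpeciesObservation
from habstat.simulate import (
    GradientParams,
    LatentPlotTruth,
    ObserverModel,
    SimulationConfig,
    expert_observer,
    generate_protocol,
    generate_truth,
    nonexpert_observer,
    sample_plot_locations,
    simulate_observation,
    simulate_survey,
)

SQUARE = box(0.0, 0.0, 100.0, 100.0)


def _flat_detect(p):
    return {c: p for c in ("woody_species", "herbaceous_species", "structure", "pressure")}


def test_generate_protocol_cardinalities_and_determinism():
    cfg = SimulationConfig(seed=7, n_structure_items=10, n_typical_species=8, n_pressure_codes=6)
    proto1 = generate_protocol(cfg, seed=7)
    proto2 = generate_protocol(cfg, seed=7)
    assert proto1 == proto2
    assert len(proto1.sf_checklist) == 10
    assert len(proto1.typical_species) == 8 + cfg.n_absent_species
    assert len(proto1.pressure_catalogue) == 6
    # distinct seeds give distinct protocols with high probability
    protos = {generate_protocol(cfg, seed=s) for s in range(100)}
    assert len(protos) > 50


def test_observer_model_validation():
    with pytest.raises(ValueError, match="detect_prob"):
        ObserverModel(status="expert", detect_prob={"structure": 0.5})
    with pytest.raises(ValueError, match="edge_scale_lambda"):
        expert_observer(edge_scale_lambda=-1.0)
    m = nonexpert_observer(season_factor=0.5)
    assert m.effective_detect_prob("herbaceous_species") == pytest.approx(0.35 * 0.5)
    assert m.effective_detect_prob("woody_species") == pytest.approx(0.85)


def test_placement_contract_and_bias():
    rng_pts = sample_plot_locations(SQUARE, nonexpert_observer(), 200, seed=1)
    assert rng_pts.shape == (200, 2)
    d = shapely.distance(SQUARE.boundary, shapely.points(rng_pts))
    assert (d >= 0).all()
    assert shapely.covers(SQUARE, shapely.points(rng_pts)).all()

    uniform = sample_plot_locations(SQUARE, expert_observer(), 2000, seed=2)
    d_unif = shapely.distance(SQUARE.boundary, shapely.points(uniform)).mean()
    # uniform mean distance to the edge of a square of side L is L/6
    assert d_unif == pytest.approx(100 / 6, abs=1.0)

    biased = sample_plot_locations(SQUARE, nonexpert_observer(edge_scale_lambda=1.0), 500, seed=3)
    d_bias = shapely.distance(SQUARE.boundary, shapely.points(biased)).mean()
    assert d_bias < d_unif

    huge_lambda = sample_plot_locations(
        SQUARE, nonexpert_observer(edge_scale_lambda=1e9), 2000, seed=4
    )
    d_huge = shapely.distance(SQUARE.boundary, shapely.points(huge_lambda)).mean()
    assert d_huge == pytest.approx(d_unif, abs=1.5)


def test_placement_stall_error():
    with pytest.raises(RuntimeError, match="lambda"):
        sample_plot_locations(
            SQUARE, nonexpert_observer(edge_scale_lambda=1e-4), 5, seed=0, max_proposals=5000
        )


def test_truth_gradient_limits():
    cfg = SimulationConfig(seed=0)
    proto = generate_protocol(cfg, seed=0)
    flat = GradientParams(alpha=0.3, beta=0.0)
    t_edge = generate_truth((0.5, 50.0), proto, flat, SQUARE, seed=5)
    t_core = generate_truth((50.0, 50.0), proto, flat, SQUARE, seed=5)
    # beta = 0: same presence probability everywhere (same rng -> same draw)
    assert t_edge.structures_true == t_core.structures_true

    steep = GradientParams(alpha=-0.2, beta=0.5)
    assert steep.presence_prob(50.0) > 0.997  # logistic argument > 6
    t = generate_truth((50.0, 50.0), proto, steep, SQUARE, seed=6)
    assert len(t.structures_true) == len(proto.sf_checklist)

    # determinism
    assert generate_truth((30.0, 40.0), proto, steep, SQUARE, seed=9) == generate_truth(
        (30.0, 40.0), proto, steep, SQUARE, seed=9
    )


def test_absent_species_never_true():
    cfg = SimulationConfig(seed=11)
    dataset, truths = simulate_survey(cfg, return_truth=True)
    absent = cfg.absent_species_ids()
    assert absent
    for truth in truths.values():
        assert not (truth.items_true & absent)


def test_perfect_observer_reproduces_truth():
    cfg = SimulationConfig(seed=2)
    proto = generate_protocol(cfg, seed=2)
    truth = generate_truth((40.0, 40.0), proto, cfg.gradient, SQUARE, seed=3)
    perfect = ObserverModel(status="expert", detect_prob=_flat_detect(1.0))
    rec = simulate_observation(truth, perfect, "p1", seed=4, protocol=proto)
    assert rec.structures_present == truth.structures_true
    assert {o.species_id for o in rec.species_obs} == set(truth.species_true)
    assert set(rec.pressures) == set(truth.pressures_true)

    blind = ObserverModel(status="non_expert", detect_prob=_flat_detect(0.0))
    rec0 = simulate_observation(truth, blind, "p2", seed=4, protocol=proto)
    assert not rec0.structures_present and not rec0.species_obs and not rec0.pressures


def test_detection_thinning_binomial_mean():
    # 20-item truth observed at p = 0.5: mean recorded richness 10 +/- 0.3
    cfg = SimulationConfig(seed=3, n_structure_items=20)
    proto = generate_protocol(cfg, seed=3)
    truth = LatentPlotTruth(
        location=(50.0, 50.0),
        distance_to_edge=50.0,
        structures_true=frozenset(i.item_id for i in proto.sf_checklist),
        species_true={},
        pressures_true=(),
    )
    half = ObserverModel(status="non_expert", detect_prob=_flat_detect(0.5))
    rng = np.random.default_rng(8)
    richness = [
        len(simulate_observation(truth, half, "p", rng, proto).structures_present)
        for _ in range(2000)
    ]
    assert np.mean(richness) == pytest.approx(10.0, abs=0.3)


def test_false_positive_records_get_lowest_classes():
    cfg = SimulationConfig(seed=4)
    proto = generate_protocol(cfg, seed=4)
    empty_truth = LatentPlotTruth(
        location=(50.0, 50.0),
        distance_to_edge=50.0,
        structures_true=frozenset(),
        species_true={},
        pressures_true=(),
    )
    fp = ObserverModel(
        status="non_expert", detect_prob=_flat_detect(0.0), false_positive_rate=1.0
    )
    rec = simulate_observation(empty_truth, fp, "p", seed=5, protocol=proto)
    assert all(o == SpeciesObservation(o.species_id, "rare", "poor") for o in rec.species_obs)
    assert all(r.intensity == "low" for r in rec.pressures)


def test_survey_bookkeeping_and_determinism():
    cfg = SimulationConfig(seed=6, n_experts=2, n_expert_plots=6, n_nonexpert_plots=30)
    ds1 = simulate_survey(cfg)
    ds2 = simulate_survey(cfg)
    assert ds1 == ds2  # byte-identical given the seed
    assert len(ds1.plots) == 36
    observers = {p.observer_id for p in ds1.plots}
    assert len(observers) == 32  # 2 experts + 30 volunteers
    per_volunteer = [
        p.observer_id for p in ds1.plots if p.observer_status == "non_expert"
    ]
    assert len(per_volunteer) == len(set(per_volunteer))  # one plot each


def test_expert_richness_exceeds_nonexpert_in_most_seeds():
    from habstat.quality import build_incidence, per_plot_richness

    wins = 0
    n_seeds = 40
    for seed in range(n_seeds):
        ds = simulate_survey(SimulationConfig(seed=seed))
        table = build_incidence(ds, "structure_function")
        richness = per_plot_richness(table)
        means = {}
        for status in ("expert", "non_expert"):
            pids = [p.plot_id for p in ds.plots_by_status(status)]
            means[status] = np.mean([richness[p] for p in pids])
        if means["expert"] > means["non_expert"]:
            wins += 1
    assert wins >= 0.95 * n_seeds
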