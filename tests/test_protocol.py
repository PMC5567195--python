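"""Classification rules: worked examples, literal-rule oracles, monotonicity."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habstat.protocol import (
    ABUNDANCE_LEVELS,
    INTENSITY_LEVELS,
    VITALITY_LEVELS,
    HabitatProtocol,
    ChecklistItem,
    PressureRecord,
    SpeciesObservation,
    StatusClass,
    assess_plot,
    classify_future_prospects,
    classify_structures_functions,
    classify_typical_species,
    score_typical_species,
)
from conftest import make_plot
from habstat.protocol import TypicalSpecies

# read-only protocol for hypothesis-driven tests (fixtures are function-scoped)
_WEIGHTED_PROTOCOL = HabitatProtocol(
    "2120",
    (ChecklistItem("A"),),
    typical_species=(
        TypicalSpecies("spA", 2.0),
        TypicalSpecies("spB", 1.0),
        TypicalSpecies("spC", 1.0),
    ),
)


# --- independent transliterations of the printed classification rules -----

def sf_rule_oracle(n_present: int, size: int) -> str:
    frac = n_present / size
    if frac > 0.5:  # more than 50 % present
        return "FV"
    if 0.25 <= frac <= 0.5:  # between 25 % and 50 %
        return "U1"
    return "U2"  # less than 25 %


def pt_rule_oracle(intensities) -> str:
    n = len(intensities)
    n_low_med = sum(1 for i in intensities if i in ("low", "medium"))
    if n == 0 or (n == 1 and n_low_med == 1):
        return "FV"
    if n <= 3 and n_low_med == n:
        return "U1"
    return "U2"  # at least one high, or more than three records


@pytest.mark.parametrize(
    "n,size,expected",
    [
        (6, 10, StatusClass.FV),
        (5, 10, StatusClass.U1),  # 50 % is not "more than 50 %"
        (2, 10, StatusClass.U2),
        (0, 7, StatusClass.U2),
        (1, 4, StatusClass.U1),  # 25 % boundary is inside the middle band
    ],
)
def test_structures_functions_thresholds(n, size, expected):
    assert classify_structures_functions(n, size) is expected


def test_structures_functions_matches_rule_text_exhaustively():
    for size in range(1, 13):
        for n in range(size + 1):
            assert (
                classify_structures_functions(n, size).name == sf_rule_oracle(n, size)
            ), (n, size)


@pytest.mark.parametrize(
    "bad_args",
    [(-1, 5), (6, 5), (0, 0), (1, -2)],
)
def test_structures_functions_invalid_inputs(bad_args):
    with pytest.raises(ValueError, match="n_present|checklist_size"):
        classify_structures_functions(*bad_args)


@pytest.mark.parametrize(
    "intensities,expected",
    [
        ([], StatusClass.FV),
        (["medium"], StatusClass.FV),
        (["low", "low", "medium"], StatusClass.U1),
        (["high"], StatusClass.U2),
        (["medium"] * 4, StatusClass.U2),
    ],
)
def test_future_prospects_rule(intensities, expected):
    records = [PressureRecord(f"P{i}", inten) for i, inten in enumerate(intensities)]
    assert classify_future_prospects(records) is expected


def test_future_prospects_matches_rule_text_on_all_small_multisets():
    for k in range(6):
        for combo in itertools.combinations_with_replacement(INTENSITY_LEVELS, k):
            records = [PressureRecord(f"P{i}", inten) for i, inten in enumerate(combo)]
            assert classify_future_prospects(records).name == pt_rule_oracle(combo), combo


def test_future_prospects_role_does_not_change_count():
    recs = [
        PressureRecord("P1", "low", "pressure"),
        PressureRecord("P2", "medium", "both"),
    ]
    # two low/medium records -> U1 regardless of pressure/threat/both roles
    assert classify_future_prospects(recs) is StatusClass.U1


def test_typical_species_worked_example(tiny_protocol):
    # weights spA=2, spB=1, spC=1; observed spA(frequent, good), spC(rare, moderate):
    # (2*0.75*1.0 + 1*0.25*0.75) / 4 = 0.421875
    obs = [
        SpeciesObservation("spA", "frequent", "good"),
        SpeciesObservation("spC", "rare", "moderate"),
    ]
    score = score_typical_species(obs, tiny_protocol)
    assert score == pytest.approx(0.421875, abs=1e-12)
    assert classify_typical_species(score) is StatusClass.U1


def test_typical_species_score_limits(tiny_protocol):
    full = [
        SpeciesObservation(s.species_id, "abundant", "good")
        for s in tiny_protocol.typical_species
    ]
    assert score_typical_species(full, tiny_protocol) == pytest.approx(1.0)
    assert score_typical_species([], tiny_protocol) == 0.0
    assert classify_typical_species(1.0) is StatusClass.FV
    assert classify_typical_species(0.0) is StatusClass.U2


def test_unknown_species_ignored_with_warning(tiny_protocol, caplog):
    obs = [SpeciesObservation("ghost", "abundant", "good")]
    with caplog.at_level("WARNING"):
        assert score_typical_species(obs, tiny_protocol) == 0.0
    assert "ghost" in caplog.text


def test_empty_typical_species_protocol_errors():
    protocol = HabitatProtocol("2120", (ChecklistItem("A"),))
    with pytest.raises(ValueError, match="typical-species"):
        score_typical_species([], protocol)


def test_categoricals_case_insensitive():
    obs = SpeciesObservation("x", "Abundant", "GOOD")
    assert (obs.abundance, obs.vitality) == ("abundant", "good")
    with pytest.raises(ValueError, match="intensity"):
        PressureRecord("P1", "severe")


def test_assess_plot_compositions(tiny_protocol):
    best = make_plot(
        "p1",
        structures=("A", "B"),
        species=[(s.species_id, "abundant", "good") for s in tiny_protocol.typical_species],
    )
    r = assess_plot(best, tiny_protocol)
    assert (r.sf_status, r.ts_status, r.pt_status, r.overall_status) == (
        StatusClass.FV,
        StatusClass.FV,
        StatusClass.FV,
        StatusClass.FV,
    )
    assert r.sf_fraction == pytest.approx(2 / 3)

    no_species = make_plot("p2", structures=("A", "B"))
    assert assess_plot(no_species, tiny_protocol).overall_status is StatusClass.U2

    pressured = make_plot(
        "p3",
        structures=(),
        species=[(s.species_id, "abundant", "good") for s in tiny_protocol.typical_species],
        pressures=[("P1", "high")],
    )
    r = assess_plot(pressured, tiny_protocol)
    assert r.ts_status is StatusClass.FV and r.overall_status is StatusClass.U2


def test_assess_plot_habitat_mismatch(tiny_protocol):
    plot = make_plot("p1", habitat_code="9560")
    with pytest.raises(ValueError, match="9560.*2120|2120.*9560"):
        assess_plot(plot, tiny_protocol)


def test_assess_plot_deterministic(tiny_protocol):
    plot = make_plot("p1", structures=("A",), species=[("spA", "frequent", "good")])
    assert assess_plot(plot, tiny_protocol) == assess_plot(plot, tiny_protocol)


# --- monotonicity properties ----------------------------------------------

@settings(derandomize=True, deadline=None, max_examples=200)
@given(size=st.integers(1, 15), n=st.integers(0, 14))
def test_adding_structures_never_worsens_status(size, n):
    n = min(n, size - 1) if size > 1 else 0
    if n + 1 > size:
        return
    assert classify_structures_functions(n + 1, size) <= classify_structures_functions(n, size)


@settings(derandomize=True, deadline=None, max_examples=200)
@given(
    intensities=st.lists(st.sampled_from(INTENSITY_LEVELS), max_size=6),
    extra=st.sampled_from(INTENSITY_LEVELS),
)
def test_adding_pressures_never_improves_status(intensities, extra):
    recs = [PressureRecord(f"P{i}", v) for i, v in enumerate(intensities)]
    more = recs + [PressureRecord("Px", extra)]
    assert classify_future_prospects(more) >= classify_future_prospects(recs)


@settings(derandomize=True, deadline=None, max_examples=200)
@given(
    a_idx=st.integers(0, 3),
    v_idx=st.integers(0, 2),
    other=st.tuples(st.integers(0, 3), st.integers(0, 2)),
)
def test_raising_abundance_or_vitality_never_lowers_score(a_idx, v_idx, other):
    protocol = _WEIGHTED_PROTOCOL

    def build(ai, vi):
        return [
            SpeciesObservation("spA", ABUNDANCE_LEVELS[ai], VITALITY_LEVELS[vi]),
            SpeciesObservation("spB", ABUNDANCE_LEVELS[other[0]], VITALITY_LEVELS[other[1]]),
        ]

    base = score_typical_species(build(a_idx, v_idx), protocol)
    if a_idx < 3:
        assert score_typical_species(build(a_idx + 1, v_idx), protocol) >= base
    if v_idx < 2:
        assert score_typical_species(build(a_idx, v_idx + 1), protocol) >= base


@settings(derandomize=True, deadline=None, max_examples=100)
@given(perm_seed=st.randoms(use_true_random=False))
def test_species_score_order_invariant(perm_seed):
    tiny_protocol = _WEIGHTED_PROTOCOL
    obs = [
        SpeciesObservation("spA", "frequent", "good"),
        SpeciesObservation("spB", "rare", "poor"),
        SpeciesObservation("spC", "occasional", "moderate"),
    ]
    shuffled = obs[:]
    perm_seed.shuffle(shuffled)
    assert score_typical_species(shuffled, tiny_protocol) == pytest.approx(
        score_typical_species(obs, tiny_protocol)
    )
    assert 0.0 <= score_typical_species(obs, tiny_protocol) <= 1.0
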