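import pytest

from habstat.protocol import (
    ChecklistItem,
    HabitatProtocol,
    PlotRecord,
    PressureActivity,
    PressureRecord,
    SpeciesObservation,
    TypicalSpecies,
)
from habstat.quality import SurveyDataset


@pytest.fixture
def tiny_protocol() -> HabitatProtocol:
    """Three checklist items, three weighted species (2/1/1), three pressure codes."""
    return HabitatProtocol(
        habitat_code="2120",
        sf_checklist=(
            ChecklistItem("A", "item A"),
            ChecklistItem("B", "item B"),
            ChecklistItem("C", "item C", item_class="degradation_absence"),
        ),
        typical_species=(
            TypicalSpecies("spA", 2.0),
            TypicalSpecies("spB", 1.0, growth_form="herbaceous"),
            TypicalSpecies("spC", 1.0, growth_form="herbaceous"),
        ),
        pressure_catalogue=(
            PressureActivity("P1", "grazing"),
            PressureActivity("P2", "roads"),
            PressureActivity("P3", "sports"),
        ),
    )


def make_plot(
    plot_id,
    observer_id="obs1",
    status="expert",
    structures=(),
    species=(),
    pressures=(),
    location=(50.0, 50.0),
    habitat_code="2120",
):
    return PlotRecord(
        plot_id=plot_id,
        habitat_code=habitat_code,
        observer_id=observer_id,
        observer_status=status,
        location=location,
        structures_present=frozenset(structures),
        species_obs=tuple(SpeciesObservation(*s) for s in species),
        pressures=tuple(PressureRecord(*p) for p in pressures),
    )


@pytest.fixture
def tiny_dataset(tiny_protocol) -> SurveyDataset:
    """Two expert and three non-expert plots with known item overlaps."""
    plots = [
        make_plot("e1", "exp1", "expert", structures=("A", "B"), species=[("spA", "abundant", "good")], pressures=[("P1", "low")]),
        make_plot("e2", "exp2", "expert", structures=("A",), species=[("spB", "frequent", "moderate")]),
        make_plot("n1", "vol1", "non_expert", structures=("A",), species=[("spA", "rare", "poor")], pressures=[("P1", "low")]),
        make_plot("n2", "vol2", "non_expert", structures=("B", "C"), pressures=[("P2", "high")]),
        make_plot("n3", "vol3", "non_expert", structures=("A",), species=[("spC", "occasional", "good")]),
    ]
    return SurveyDataset(
        site_code="S1", habitat_code="2120", plots=plots, protocol=tiny_protocol
    )
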