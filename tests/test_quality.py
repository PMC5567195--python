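"""Expert vs. non-expert comparison metrics against hand counts and recount oracles."""

import numpy as np
import pytest

from habstat.quality import (
    SurveyDataset,
    accuracy,
    build_incidence,
    compare_groups,
    completeness,
    flag_low_support,
    per_plot_richness,
    pooled_items,
    support_counts,
)
from conftest import make_plot


def test_incidence_transcription(tiny_protocol):
    ds = SurveyDataset(
        "S1",
        "2120",
        [
            make_plot("p1", structures=("A", "B")),
            make_plot("p2", "obs2", "non_expert", structures=("B",)),
        ],
        tiny_protocol,
    )
    table = build_incidence(ds, "structure_function")
    assert list(table.matrix.columns) == ["A", "B", "C"]  # full checklist kept
    assert table.matrix.loc["p1"].tolist() == [1, 1, 0]
    assert table.matrix.loc["p2"].tolist() == [0, 1, 0]
    assert len(table.matrix) == len(ds.plots)


def test_incidence_empty_plot_and_unknown_kind(tiny_dataset):
    ds = tiny_dataset
    table = build_incidence(ds, "typical_species")
    # plot n2 recorded no species -> all-zero row
    assert table.matrix.loc["n2"].sum() == 0
    with pytest.raises(ValueError, match="item_kind"):
        build_incidence(ds, "bird_song")


def test_per_plot_richness_matches_recount(tiny_dataset):
    rng = np.random.default_rng(42)
    table = build_incidence(tiny_dataset, "structure_function")
    # independent recount: sum over columns per row
    richness = per_plot_richness(table)
    for pid in table.matrix.index:
        assert richness[pid] == sum(
            int(table.matrix.at[pid, c]) for c in table.matrix.columns
        )
    # and on a random 0/1 table
    table.matrix.iloc[:, :] = rng.integers(0, 2, size=table.matrix.shape)
    richness = per_plot_richness(table)
    for pid in table.matrix.index:
        assert richness[pid] == int(table.matrix.loc[pid].to_numpy().sum())


def test_pooled_items_is_group_union(tiny_dataset):
    table = build_incidence(tiny_dataset, "structure_function")
    assert pooled_items(table, "expert") == {"A", "B"}
    assert pooled_items(table, "non_expert") == {"A", "B", "C"}
    richness = per_plot_richness(table)
    non_plots = [p.plot_id for p in tiny_dataset.plots_by_status("non_expert")]
    assert len(pooled_items(table, "non_expert")) >= max(richness[p] for p in non_plots)


def test_completeness_identical_groups(tiny_protocol):
    plots = [
        make_plot("e1", "x1", "expert", structures=("A", "B")),
        make_plot("n1", "v1", "non_expert", structures=("A", "B")),
    ]
    ds = SurveyDataset("S1", "2120", plots, tiny_protocol)
    comp = completeness(ds, "structure_function")
    assert comp["per_plot"] == pytest.approx(1.0)
    assert comp["pooled"] == pytest.approx(1.0)


def test_completeness_zero_and_undefined(tiny_protocol):
    plots = [
        make_plot("e1", "x1", "expert", structures=("A",)),
        make_plot("n1", "v1", "non_expert"),
    ]
    ds = SurveyDataset("S1", "2120", plots, tiny_protocol)
    comp = completeness(ds, "structure_function")
    assert comp["per_plot"] == 0.0 and comp["pooled"] == 0.0
    # expert denominator zero -> undefined ratio
    ds_bad = SurveyDataset(
        "S1",
        "2120",
        [
            make_plot("e1", "x1", "expert"),
            make_plot("n1", "v1", "non_expert", structures=("A",)),
        ],
        tiny_protocol,
    )
    with pytest.raises(ValueError, match="expert"):
        completeness(ds_bad, "structure_function")


def test_completeness_binomial_recovery(tiny_protocol):
    # detection p_non = 0.45 vs p_exp = 0.9 over 500 plots/group on a
    # 10-item always-true checklist -> per-plot ratio near 0.5
    from habstat.studies import completeness_recovery_study

    res = completeness_recovery_study(n_plots_per_group=500, seed=11)
    assert res["per_plot_completeness"] == pytest.approx(0.5, abs=0.07)


def test_accuracy_hand_counts(tiny_protocol):
    plots = [
        make_plot("e1", "x1", "expert", structures=("A", "B")),
        make_plot("n1", "v1", "non_expert", structures=("A", "B")),
        make_plot("n2", "v2", "non_expert", structures=("C",)),
    ]
    ds = SurveyDataset("S1", "2120", plots, tiny_protocol)
    # non-expert items {A,B,C}; expert items {A,B}; C uncorroborated -> 2/3
    assert accuracy(ds, "structure_function") == pytest.approx(2 / 3)
    # reference set corroborates C
    assert accuracy(ds, "structure_function", reference_set={"C"}) == 1.0
    # subset case -> 1.0
    ds2 = SurveyDataset("S1", "2120", plots[:2], tiny_protocol)
    assert accuracy(ds2, "structure_function") == 1.0


def test_accuracy_no_overlap_and_undefined(tiny_protocol):
    plots = [
        make_plot("e1", "x1", "expert", structures=("A",)),
        make_plot("n1", "v1", "non_expert", structures=("B",)),
    ]
    ds = SurveyDataset("S1", "2120", plots, tiny_protocol)
    assert accuracy(ds, "structure_function") == 0.0
    ds_empty = SurveyDataset(
        "S1",
        "2120",
        [plots[0], make_plot("n2", "v2", "non_expert")],
        tiny_protocol,
    )
    with pytest.raises(ValueError, match="non-experts"):
        accuracy(ds_empty, "structure_function")


def test_support_counts_distinct_observers(tiny_protocol):
    plots = [
        make_plot("e1", "x1", "expert", structures=("A",)),
        # same observer reports A in two plots -> still support 1
        make_plot("n1", "v1", "non_expert", structures=("A",)),
        make_plot("n2", "v1", "non_expert", structures=("A",)),
        make_plot("n3", "v2", "non_expert", structures=("A", "B")),
        make_plot("n4", "v3", "non_expert", structures=("A",)),
    ]
    ds = SurveyDataset("S1", "2120", plots, tiny_protocol)
    support = support_counts(ds, "structure_function")
    assert support == {"A": 3, "B": 1}


def test_support_counts_matches_bruteforce(tiny_dataset):
    support = support_counts(tiny_dataset, "structure_function")
    for item, n in support.items():
        observers = {
            p.observer_id
            for p in tiny_dataset.plots
            if p.observer_status == "non_expert" and item in p.structures_present
        }
        assert n == len(observers)


def test_flag_low_support_thresholds():
    support = {"A": 1, "B": 3, "C": 2}
    assert flag_low_support(support, 2) == {"A"}
    assert flag_low_support(support, 1) == set()
    assert flag_low_support(support, 4) == {"A", "B", "C"}
    # monotone in threshold, idempotent marking
    for k in range(1, 5):
        assert flag_low_support(support, k) <= flag_low_support(support, k + 1)
    with pytest.raises(ValueError):
        flag_low_support(support, 0)


def test_compare_groups_partition_set_algebra(tiny_dataset):
    report = compare_groups(tiny_dataset, "structure_function")
    exp = {"A", "B"}
    non = {"A", "B", "C"}
    assert report.items_shared == exp & non
    assert report.items_only_experts == exp - non
    assert report.items_only_nonexperts == non - exp
    assert report.items_shared.isdisjoint(report.items_only_experts)
    assert report.items_shared.isdisjoint(report.items_only_nonexperts)
    # pooling never loses expert items
    assert len(exp | non) >= len(exp)


def test_compare_groups_identical_groups(tiny_protocol):
    plots = [
        make_plot("e1", "x1", "expert", structures=("A", "B")),
        make_plot("n1", "v1", "non_expert", structures=("A", "B")),
    ]
    ds = SurveyDataset("S1", "2120", plots, tiny_protocol)
    r = compare_groups(ds, "structure_function")
    assert r.completeness_per_plot == pytest.approx(1.0)
    assert r.completeness_pooled == pytest.approx(1.0)
    assert r.accuracy == 1.0
    assert r.items_only_experts == frozenset() == r.items_only_nonexperts


def test_removing_flagged_items_shrinks_nonexpert_only(tiny_dataset):
    report = compare_groups(tiny_dataset, "structure_function")
    kept = report.items_only_nonexperts - report.flagged_items
    assert len(kept) <= len(report.items_only_nonexperts)


def test_dataset_validation(tiny_protocol):
    with pytest.raises(ValueError, match="at least one plot"):
        SurveyDataset("S1", "2120", [], tiny_protocol)
    with pytest.raises(ValueError, match="duplicate"):
        SurveyDataset(
            "S1", "2120", [make_plot("p1"), make_plot("p1")], tiny_protocol
        )
    with pytest.raises(ValueError, match="habitat"):
        SurveyDataset(
            "S1", "2120", [make_plot("p1", habitat_code="9560")], tiny_protocol
        )
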