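"""Monte-Carlo design checks for the survey-quality methodology.

Each routine here answers one methodological question about the pipeline by
simulation, at the study's own design sizes (a handful of expert plots vs.
tens of non-expert plots):

* is the Monte-Carlo permutation p-value exact (one-way, tiny n, full
  enumeration comparison)?
* is the permutational ANOVA's type-I error calibrated under the null on the
  unbalanced two-way design?
* does the status factor reliably detect the expert/non-expert per-plot
  richness contrast at the study's detection probabilities?
* does the per-plot completeness estimator recover the ratio of detection
  probabilities?
* does the edge-distance permutation test detect edge-biased placement, and
  keep its size under uniform placement?
* does low-support flagging capture unrepeated false-positive records?

The routines are deterministic given their seed and are used both by the
analysis drivers and by the acceptance machinery.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Optional

import numpy as np
from shapely.geometry import box

from .permstats import AnovaDesign, exhaustive_oneway_perm_p, perm_anova
from .quality import build_incidence, completeness, flag_low_support, per_plot_richness, support_counts
from .simulate import (
    GradientParams,
    SimulationConfig,
    expert_observer,
    nonexpert_observer,
    sample_plot_locations,
    simulate_survey,
)
from .spatial import permutation_mean_diff_test

__all__ = [
    "oneway_exactness_study",
    "null_calibration_study",
    "status_power_study",
    "completeness_recovery_study",
    "edge_bias_study",
    "false_positive_flagging_study",
]

# Detection-contrast conditions of the headline comparison: a 10-item
# always-true checklist observed at 0.9 (expert) vs 0.45 (non-expert).
_FLAT_GRADIENT = GradientParams(alpha=12.0, beta=0.0, pressure_mean_edge=0.0)


def _contrast_config(seed: int, n_expert: int, n_nonexpert: int, p_expert=0.9, p_non=0.45):
    return SimulationConfig(
        seed=seed,
        n_structure_items=10,
        n_expert_plots=n_expert,
        n_nonexpert_plots=n_nonexpert,
        n_experts=2,
        expert_model=expert_observer(
            detect_prob={c: p_expert for c in ("woody_species", "herbaceous_species", "structure", "pressure")},
        ),
        nonexpert_model=nonexpert_observer(
            detect_prob={c: p_non for c in ("woody_species", "herbaceous_species", "structure", "pressure")},
            false_positive_rate=0.0,
            edge_scale_lambda=None,
        ),
        gradient=_FLAT_GRADIENT,
    )


def oneway_exactness_study(
    n_datasets: int = 10,
    n_permutations: int = 20_000,
    seed: int = 0,
) -> Dict[str, float]:
    """Monte-Carlo vs. exhaustive one-way permutation p on tiny datasets.

    Draws small two-group count datasets (total n <= 8), computes the
    permutation p-value both by Monte Carlo and by full enumeration of all
    group assignments, and reports the maximum absolute deviation.
    """
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(n_datasets):
        n_a = int(rng.integers(2, 4))
        n_b = int(rng.integers(2, 9 - n_a))
        y = rng.poisson(4.0, size=n_a + n_b).astype(float)
        labels = np.array(["a"] * n_a + ["b"] * n_b)
        if np.ptp(y) == 0:  # degenerate draw: all counts equal
            y[0] += 1.0
        exact = exhaustive_oneway_perm_p(y, labels)
        design = AnovaDesign(
            response=y,
            factor_status=labels,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        mc = perm_anova(design, factors=("status",)).factors["status"].p_value
        max_dev = max(max_dev, abs(mc - exact))
    return {"max_abs_deviation": max_dev, "n_datasets": n_datasets}


def null_calibration_study(
    n_sims: int = 500,
    n_permutations: int = 999,
    seed: int = 0,
    n_expert: int = 6,
    n_nonexpert: int = 30,
    n_habitats: int = 4,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Type-I error of the two-way permutational ANOVA under the null.

    Simulates count responses independent of both factors (iid Poisson, mean
    5) on the unbalanced design (``n_expert`` expert + ``n_nonexpert``
    non-expert plots in each of ``n_habitats`` habitat types) and reports the
    rejection rate of each factor at level ``alpha``.
    """
    rng = np.random.default_rng(seed)
    per_hab = n_expert + n_nonexpert
    status = np.array((["expert"] * n_expert + ["non_expert"] * n_nonexpert) * n_habitats)
    habitat = np.repeat([f"H{i}" for i in range(n_habitats)], per_hab)
    rej = {"status": 0, "habitat": 0}
    for _ in range(n_sims):
        y = rng.poisson(5.0, size=status.size).astype(float)
        design = AnovaDesign(
            response=y,
            factor_status=status,
            factor_habitat=habitat,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        res = perm_anova(design, factors=("status", "habitat"))
        for f_name in rej:
            if res.factors[f_name].p_value <= alpha:
                rej[f_name] += 1
    return {
        "rejection_rate_status": rej["status"] / n_sims,
        "rejection_rate_habitat": rej["habitat"] / n_sims,
        "n_sims": n_sims,
        "alpha": alpha,
    }


def status_power_study(
    n_replicates: int = 200,
    n_permutations: int = 999,
    seed: int = 0,
    p_threshold: float = 0.01,
) -> Dict[str, float]:
    """Power of the status factor under the study's detection contrast.

    Each replicate simulates a survey with 6 expert plots (detection 0.9)
    and 30 non-expert plots (detection 0.45) on a 10-item always-present
    checklist, runs the one-way permutational ANOVA on per-plot
    structures-and-functions richness, and checks p <= ``p_threshold``.
    """
    rng = np.random.default_rng(seed)
    n_sig = 0
    for _ in range(n_replicates):
        cfg = _contrast_config(int(rng.integers(2**31 - 1)), n_expert=6, n_nonexpert=30)
        dataset = simulate_survey(cfg)
        inc = build_incidence(dataset, "structure_function")
        richness = per_plot_richness(inc)
        pids = sorted(richness)
        design = AnovaDesign(
            response=[richness[p] for p in pids],
            factor_status=[inc.observer_status[p] for p in pids],
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        p = perm_anova(design, factors=("status",)).factors["status"].p_value
        if p <= p_threshold:
            n_sig += 1
    return {
        "power": n_sig / n_replicates,
        "n_replicates": n_replicates,
        "p_threshold": p_threshold,
    }


def completeness_recovery_study(
    n_plots_per_group: int = 500,
    seed: int = 0,
) -> Dict[str, float]:
    """Per-plot completeness vs. the detection-probability ratio.

    With expert detection 0.9 and non-expert detection 0.45 on an
    always-present checklist, per-plot completeness should estimate
    0.45 / 0.9 = 0.5.
    """
    cfg = _contrast_config(seed, n_expert=n_plots_per_group, n_nonexpert=n_plots_per_group)
    dataset = simulate_survey(cfg)
    comp = completeness(dataset, "structure_function")
    return {
        "per_plot_completeness": comp["per_plot"],
        "expected_ratio": 0.45 / 0.9,
        "n_plots_per_group": n_plots_per_group,
    }


def edge_bias_study(
    n_sims: int = 100,
    n_permutations: int = 999,
    seed: int = 0,
    lambda_nonexpert: Optional[float] = 5.0,
    n_per_group: int = 30,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Detection rate of the edge-distance permutation test.

    Experts place plots uniformly in a 100 m square patch; non-experts with
    exponential edge bias of scale ``lambda_nonexpert`` (``None`` simulates
    the no-bias null).  Reports the fraction of simulations rejecting at
    ``alpha``.
    """
    rng = np.random.default_rng(seed)
    patch = box(0.0, 0.0, 100.0, 100.0)
    expert = expert_observer()
    nonexp = nonexpert_observer(edge_scale_lambda=lambda_nonexpert)
    boundary = patch.boundary
    import shapely

    n_rej = 0
    for _ in range(n_sims):
        xy_e = sample_plot_locations(patch, expert, n_per_group, rng)
        xy_n = sample_plot_locations(patch, nonexp, n_per_group, rng)
        d_e = shapely.distance(boundary, shapely.points(xy_e))
        d_n = shapely.distance(boundary, shapely.points(xy_n))
        _, p = permutation_mean_diff_test(
            d_e, d_n, n_permutations=n_permutations, seed=int(rng.integers(2**31 - 1))
        )
        if p <= alpha:
            n_rej += 1
    return {
        "rejection_rate": n_rej / n_sims,
        "n_sims": n_sims,
        "alpha": alpha,
        "lambda_nonexpert": float("inf") if lambda_nonexpert is None else lambda_nonexpert,
    }


def false_positive_flagging_study(
    n_seeds: int = 100,
    seed: int = 0,
    false_positive_rate: float = 0.01,
    n_nonexpert: int = 30,
) -> Dict[str, float]:
    """Capture rate of low-support flagging on simulated false positives.

    Simulates surveys with the default condition gradient and non-expert
    false positives, identifies every item whose non-expert reports are all
    spurious (absent from the plot's latent truth) and that no second
    observer repeated, and measures the fraction of those items flagged by
    ``flag_low_support`` at the default threshold of 2 observers.
    """
    rng = np.random.default_rng(seed)
    captured = total = 0
    kinds = ("structure_function", "typical_species", "pressure")
    for _ in range(n_seeds):
        cfg = SimulationConfig(
            seed=int(rng.integers(2**31 - 1)),
            n_nonexpert_plots=n_nonexpert,
            nonexpert_model=nonexpert_observer(false_positive_rate=false_positive_rate),
        )
        dataset, truths = simulate_survey(cfg, return_truth=True)
        for kind in kinds:
            support = support_counts(dataset, kind)
            flagged = flag_low_support(support, min_observers=2)
            # spurious records: items recorded although absent from the
            # plot's latent truth; "unrepeated" = no second observer
            # reported the same item (non-expert support 1)
            spurious_items: set = set()
            for plot in dataset.plots_by_status("non_expert"):
                truth_items = truths[plot.plot_id].items_true
                if kind == "structure_function":
                    items = plot.structures_present
                elif kind == "typical_species":
                    items = {o.species_id for o in plot.species_obs}
                else:
                    items = {r.activity_code for r in plot.pressures}
                spurious_items |= items - truth_items
            unrepeated_spurious = {
                item for item in spurious_items if support.get(item, 0) == 1
            }
            total += len(unrepeated_spurious)
            captured += len(unrepeated_spurious & flagged)
    return {
        "capture_rate": captured / total if total else 1.0,
        "n_spurious_items": total,
        "n_seeds": n_seeds,
    }
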