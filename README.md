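# habstat

Plot-level conservation-status assessment of Annex I habitat types and
quality analysis of citizen-science (non-expert) survey data.

EU Member States assess the conservation status of protected habitat types
(Habitats Directive, Article 17) from field protocols completed on sample
plots: a habitat-specific checklist of **specific structures and functions**,
a weighted list of **typical species** recorded with abundance and vitality
classes, and the **pressures and threats** acting on the plot, each with a
low/medium/high intensity.  Each criterion maps to one of three ordered
status classes — FV (Favourable), U1 (Unfavourable–Inadequate), U2
(Unfavourable–Bad).  This package is for monitoring scientists and
citizen-science coordinators who want to (a) run that classification
reproducibly and (b) quantify whether volunteer-collected protocols are good
enough to feed it.

## What it computes

**Classification rules** (`habstat.protocol`). With `p` the fraction of
checklist items present: FV if `p > 0.5`, U1 if `0.25 ≤ p ≤ 0.5`, U2 if
`p < 0.25`.  Future prospects: FV with no pressure/threat records (or a
single low/medium one), U2 with any high-intensity record or more than three
records, U1 otherwise.  The typical-species score is a normalised weighted
sum, `score = Σ w_s · a_s · v_s / Σ w_s` with ordinal multipliers
`a(rare…abundant) = 0.25…1.0`, `v(poor…good) = 0.5…1.0`, classified with the
same 50 %/25 % thresholds.  A plot's overall status is the worst of the
three criteria (one-out-all-out).

**Data quality** (`habstat.quality`). Non-expert vs expert *completeness* at
two levels — mean per-plot richness ratio and pooled item-set ratio (the
"wisdom of the crowd" view) — *accuracy* (fraction of distinct non-expert
items corroborated by expert records or a regional reference set), and
*support counting*: items reported by fewer than `k` distinct non-expert
observers (default `k = 2`, i.e. unrepeated singletons) are flagged as
candidate outliers, never deleted.

**Inference** (`habstat.permstats`, `habstat.spatial`). Permutational ANOVA
(one-way, and two-way main effects with sequential/Type-II sums of squares
for the unbalanced design) on per-plot counts, permuting individual plots,
5000 permutations by default, add-one p-values
`p = (#{F* ≥ F} + 1)/(B + 1)`; and a permutation test on the difference in
mean distance from plot locations to the habitat-patch boundary, which
quantifies edge-biased plot placement.

**Synthetic surveys** (`habstat.simulate`). A generator with a latent
edge-to-core condition gradient, class-specific detection probabilities
(woody vs herbaceous species, checklist items, pressures), seasonally
reduced herb detectability, rare non-expert false positives and
exponential-in-distance edge-biased placement, so the whole pipeline is
testable without field data.

## Worked example

```bash
habstat simulate --seed 3 --out-dir survey --n-expert-plots 4 --n-nonexpert-plots 8
habstat run-all --protocol survey/protocol.yaml --records survey/plot_records.csv \
    --polygon survey/patch.geojson --out-dir report --n-permutations 999 --seed 5
```

or the same through the library, here at the study's full design size
(6 expert plots by 2 experts, 30 single-plot volunteers, 100 m square patch):

```python
from habstat import SimulationConfig, simulate_survey, compare_groups, compare_edge_distance

cfg = SimulationConfig(seed=3)
dataset = simulate_survey(cfg)
q = compare_groups(dataset, "structure_function")
print(round(q.completeness_per_plot, 2), round(q.completeness_pooled, 2), round(q.accuracy, 2))
edge = compare_edge_distance(dataset, cfg.patch(), n_permutations=999, seed=1)
print(round(edge.mean_dist_expert, 1), round(edge.mean_dist_nonexpert, 1), edge.p_value)
```

prints

```
0.47 1.0 1.0
20.3 3.9 0.001
```

i.e. each volunteer plot recovers about half the checklist information an
expert plot does (`0.47`), yet pooled over all volunteers the group recovers
the full expert item set (`1.0`) with no uncorroborated items (`1.0`); and
volunteer plots sit ~3.9 m from the patch edge against ~20.3 m for experts,
a placement difference the permutation test calls significant (`p = 0.001`).

The numbered drivers under `analysis/` run the full study pipeline on four
simulated habitat types (two sites): `01_simulate_surveys.py` →
`02_assess_plots.py` (status tallies by observer group) →
`03_quality_comparison.py` → `04_permutation_anova.py` (two-way, then
per-habitat one-way) → `05_edge_bias.py` → `06_method_validation.py`,
writing tables under `results/`.

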