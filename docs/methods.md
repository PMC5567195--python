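# Methods

## Plot-level classification model

A habitat protocol defines, per habitat type, a checklist of
structures-and-functions indicators (natural features and
absence-of-degradation items, each true/false in the field), a weighted
typical-species list, and a pressure/threat catalogue.  Plot assessment is
deterministic:

* **Structures & functions.** With fraction `p = n_present / checklist_size`:
  FV for `p > 0.5`, U1 for `p ∈ [0.25, 0.5]`, U2 for `p < 0.25`.  The
  endpoint convention follows the rule text: "more than 50 %" and "less than
  25 %" are strict, so the middle band is the closed interval.
* **Typical species.** The rule system states that weights, abundance and
  vitality all matter but prescribes no formula, so the score is this
  package's design: a normalised weighted linear form
  `Σ w_s·a(abund_s)·v(vit_s) / Σ w_s` with `a = (0.25, 0.5, 0.75, 1.0)` over
  rare→abundant and `v = (0.5, 0.75, 1.0)` over poor→good.  It is the
  simplest form that is monotone in every input, equals 1 exactly at the
  perfect plot and 0 at the empty one.  The score is classified with the
  same 50 %/25 % thresholds as the checklist criterion, for internal
  consistency; no separate thresholds exist in the rule system.
  Off-list species are ignored with a warning (volunteers record them;
  erroring would discard whole plots).
* **Pressures & threats.** FV: no records or one low/medium record; U2: any
  high-intensity record or more than three records; U1 otherwise.  Each
  record counts once whether it is a pressure, a threat or both — the rule
  counts activities, not roles.
* **Overall status** is the worst of the three criterion classes
  (one-out-all-out), the standard convention for combining Article 17
  criteria; the rule system itself only says structures and functions "play
  the major role" without giving a combiner.

All categorical inputs are case-insensitive; canonical output is lower-case
(status codes keep their FV/U1/U2 form).

## Quality metrics

Completeness is deliberately two-level because the scientific argument
contrasts exactly these views: the *individual* volunteer plot
(mean non-expert per-plot richness / mean expert per-plot richness) versus
the *crowd* (size ratio of the pooled item sets).  Accuracy is defined over
distinct items — the question is which items were reported at all, not how
often — as the fraction of distinct non-expert items present in the pooled
expert records or an optional regional reference set.  Support counts are
distinct non-expert *observers* per item (an observer repeating an item
across plots adds no support).  `flag_low_support(k=2)` marks exactly the
unrepeated singleton records; flagging never removes data — omission or
downweighting is a separate, user-invoked step.

## Permutational ANOVA

The F statistic is classical.  For the unbalanced two-way main-effects
design (no interaction, matching the study's reporting) each factor is
tested on its sequential sum of squares entered last, SS(A | B) — equivalent
to Type-II in the no-interaction model; the rule system does not state an SS
type, so this is the package's documented choice.  The null distribution
permutes the raw response vector ("permutations on individuals"),
unrestricted by default; stratified permutation within a factor's levels is
available as an option.  p-values use the add-one estimator
`(#{F* ≥ F} + 1)/(B + 1)` with `B = 5000` by default, so `p ≥ 1/(B+1)` and
is never 0; ties count as extreme (with a 1e-12 relative tolerance), which
makes the test slightly conservative on heavily tied count responses —
observed null rejection at α = 0.05 is ≈ 0.04–0.05 rather than exactly 0.05.
Zero residual variance yields an infinite-F sentinel with a warning;
single-level factors are skipped with a warning.

An exhaustive one-way enumerator (all assignments of observations to
groups) provides exact p-values at small n, used to verify the Monte-Carlo
path; for two groups F is monotone in the absolute mean difference, so the
enumeration is cross-checked against a mean-difference enumeration in the
tests, and the observed F against independent reference implementations
(scipy one-way, statsmodels Type-II two-way).

## Edge-distance comparison

Plot-placement bias is quantified as the Euclidean distance from each plot
location to the habitat-patch boundary (planar metre coordinates; geographic
data must be projected upstream; boundary points count as inside at
distance 0, avoiding knife-edge exclusion of plots laid along paths).  Group
means are compared by permuting observer-status labels over plots, two-sided
by default (the substantive claim is directional, but the test is
exploratory; one-sided alternatives are a flag).  Degenerate data (all
distances identical) return p = 1 with a warning.

## Synthetic survey generator

The generator encodes the data-generating story the analysis assumes, with
defaults at the study design's scale:

| parameter | default | meaning |
|---|---|---|
| plots | 6 expert (2 experts) vs 30 non-expert (1 each) | unbalanced design; 30–60 vs 4–15 plots per habitat is the realistic range |
| patch | 100 m square | planar stand-in for a habitat polygon |
| checklist / species / pressures | 10 / 8 (+2 locally absent) / 6 | protocol cardinalities |
| condition gradient | logistic(−0.2 + 0.08·d) | presence probability of good items vs distance-to-edge d; ≈ 0.45 at the edge, ≈ 0.98 at 50 m |
| pressures | Poisson mean 3·exp(−d/15), intensities interpolate edge (0.2/0.3/0.5) → core (0.6/0.3/0.1) | more and harsher pressures near the edge |
| expert detection | 0.9 all item classes, no false positives, uniform placement | experts sample the ecological optimum |
| non-expert detection | 0.85 woody / 0.35 herbaceous / 0.6 checklist / 0.5 pressure | woody plants are detected far more reliably than herbs |
| season_factor | 1.0 | multiplies herbaceous detectability; < 1 models surveys when herbs are dormant |
| false_positive_rate | 0.01 (non-expert) | per absent catalogue item; spurious records get the lowest classes (abundance rare, vitality poor; pressures low) — a spurious record is never an abundant, vigorous population |
| edge_scale_lambda | 5 m (non-expert), ∞ (expert) | placement acceptance ∝ exp(−d/λ) |

Two species per protocol are on the typical list but never truly present:
typical-species lists are compiled regionally, so site-locally absent
species routinely appear on them, and any record of one is necessarily a
false positive — this is what produces the unrepeated singleton records the
flagging step exists for.  Plot placement uses rejection sampling (uniform
proposals, acceptance `exp(−d/λ)`, maximal at the edge so no normalising
constant is needed) with a proposal cap that errors with advice to increase
λ.  The exponential-in-distance form was chosen for having a single
interpretable parameter and being monotone, hence easy to invert in checks.
Teams of 2–3 volunteers sharing one protocol are treated as a single
observer id.

**What the generator does not emulate** — and therefore what passing tests
do *not* establish about real data: identification errors between similar
species (false positives are independent coin flips, not confusions),
spatial autocorrelation of condition beyond the edge-distance gradient,
observer-to-observer heterogeneity within a class, multi-visit phenology,
and real protocols' habitat-specific item semantics.  With the default
gradient and detection values the simulated volunteer plots come out
somewhat harsher (more U2) than a typical field campaign; the qualitative
ordering (experts mostly FV, volunteers mostly unfavourable, crowd pooling
recovering the expert item set) is the pattern of interest, not the tally
values.

## Validation studies and problem sizes

`habstat.studies` fixes the Monte-Carlo designs used by the analysis
drivers, the test suite and `scripts/acceptance.py`:

* one-way exactness: 10 random count datasets with n ≤ 8, 20 000-permutation
  Monte-Carlo p vs full enumeration (max |Δp| ≈ 0.005);
* type-I calibration: 500 null simulations, iid Poisson(5) response on 4
  habitats × (6 expert + 30 non-expert plots), 999 permutations — rejection
  at α = 0.05 lands near 0.04–0.05 for both factors;
* power: 200 replicates of the 6-vs-30 survey at detection 0.9 vs 0.45 on a
  10-item always-present checklist — the status factor is significant at
  p ≤ 0.01 in effectively every replicate;
* completeness recovery: 500 plots per group at the same contrast recovers
  the 0.5 detection ratio to within a few hundredths;
* edge bias: 100 surveys of 30 + 30 plots, λ = 5 m vs uniform — the
  permutation test rejects essentially always under bias and at ≈ 5 % under
  the uniform null;
* false-positive capture: across 100 survey seeds, every spurious
  unrepeated record lands in the flagged set (support 1 < 2 by
  construction, so this is an end-to-end plumbing check).

These sizes keep each study in the seconds-to-a-minute range while leaving
Monte-Carlo error well inside the margins quoted above.

## Numerical choices and degenerate inputs

Rank-robust orthonormal bases (SVD with a 1e-10 relative cutoff) guard the
projection-based F computation against collinear dummy codings; effect and
residual sums of squares are clipped at 0; zero-residual cases map to the
0/∞ sentinels described above.  Permutation tie comparisons use relative
tolerance 1e-12.  Validation errors always name the offending field, row or
habitat code.  Every pipeline output embeds the run seed and a SHA-256
digest of the run configuration; the pipeline removes partial outputs on
stage failure.

## Known limitations

National-scale criteria (habitat area and range) and real habitat-specific
protocol content are out of scope.  The accuracy metric treats expert
records as ground truth, so a genuine volunteer discovery outside the
expert pool and reference set lowers measured accuracy.  The permutation
tests' slight conservativeness on tied counts is documented above rather
than corrected (mid-p or randomised tie-breaking would trade validity
guarantees for calibration).
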