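# Methods

## Scope and model

`ppiscreen` implements a network-topology marker screen and its clinical
follow-up statistics. The screen treats the interactome as an unweighted,
undirected simple graph: interaction confidence scores, direction and edge
weights are deliberately ignored (distances are hop counts), self-loops and
duplicate reports are dropped at construction with a logged count. The
screening logic itself is fully deterministic — every iteration order is
sorted by identifier and all randomness lives in the generators.

## Topological measures

* **Degree** — neighbour count.
* **Node betweenness** — fractional shortest-path counting via Brandes'
  dependency accumulation. The one-line "number of edges running through a
  node" found in parts of the applied literature is ambiguous; we use the
  standard path-fraction definition, expose the raw value via
  `normalized=False`, and normalise by `(n−1)(n−2)/2` by default (for graphs
  with fewer than 3 nodes the normalised value is defined as 0).
* **Closeness** — `r_v / farness_v` with the reachable-node count `r_v` in the
  numerator, i.e. the per-component convention: well defined on disconnected
  graphs, equal to 1 on a complete graph, 0 for isolated nodes. Published
  screens sometimes print closeness medians far above 1 (unknown, likely
  tool-specific scaling); such values cannot be mapped onto any standard
  convention, so no attempt is made to reproduce them and the convention here
  is fixed and documented instead.
* **Coreness ("K value")** — peeling in nondecreasing current-degree order;
  `kcore_subgraph(g, k)` prunes below-`k` nodes to a fixed point and is
  idempotent. Identities maintained by tests: `coreness(v) ≤ degree(v)`;
  the max-coreness node set equals the main core.
* **Edge betweenness** — same Brandes pass, accumulated per edge, unordered
  pairs counted once. Conservation identity (tested): the sum over edges
  equals the sum of pairwise shortest-path distances over connected pairs.

Brute-force oracles used only in tests enumerate every shortest path
explicitly (backtracking over BFS distance maps) and prune cores literally;
networkx provides a second, independent cross-check.

## Screening rules

Hubs: `degree > 2 × median(all degrees)`, strict. Candidates: hubs strictly
above the hub-set median of all four features (medians use the
mean-of-middle-two rule for even counts; `median_scope="all"` switches the
feature medians to the whole marker subgraph). Strictness means a node
sitting exactly at any median is excluded — a property the tests exercise.
Core extraction and edge-betweenness ranking run on the candidate-induced
subgraph by default (`eb_scope="full"` uses the whole marker subgraph
instead); ranking is descending by score with lexicographic tie-break, so the
"key interaction" is unique and reproducible.

Note a structural consequence of the hub rule: on graphs dominated by one
dense component (e.g. a clique with a short pendant) the median degree is the
clique degree and the hub set is empty. The pipeline returns an empty result
with a report rather than failing; scenarios exercising the innermost core
therefore attach a long sparse periphery or use the planted-core generator.

## Clinical statistics

IRS = percentage category × intensity with the percentage bands 0 (0%),
1 ((0,10]), 2 ((10,50]), 3 (>50) — half-open on the left since the printed
band labels are integer-valued ("1–10", "11–50"); boundary behaviour is
tested at 0, 10, 10.5, 50, 50.5. Dichotomization labels a patient "high" iff
the score strictly exceeds the cohort median for that marker (per-marker
medians; an all-equal cohort is therefore all "low"). If a marker's median
equals its maximum score, every patient is "low" and the survival comparison
for that labelling is reported as undefined instead of raising.

Chi-square (Pearson, no continuity correction by default; Yates by flag),
Spearman correlation, Kaplan–Meier and the log-rank test are delegated to
scipy and lifelines behind this module's validated surface; the tests pin
them to the closed-form 2×2 statistic `n(ad−bc)²/(r₁r₂c₁c₂)`, rank-then-
Pearson, hand-worked product-limit values and a 2000-draw permutation oracle,
and verify log-rank type-I error calibration (rejection rate in [0.03, 0.07]
at α = 0.05 over 2000 null simulations). For an additional read-out marker
compared across the four combined groups the report computes both a
chi-square on dichotomized labels and a Kruskal–Wallis test on raw IRS, since
either convention appears in practice; both are labelled.

`validate_markers` flags p < 0.05 alongside every full-precision p-value; no
multiplicity correction is applied (the validation is confirmatory for a
pre-selected pair, mirroring common practice; users testing many covariates
should correct downstream).

## Synthetic data

**Network.** Preferential attachment: a path seed on `attach_m` nodes, then
each new node attaches `attach_m` edges to distinct existing nodes with
probability ∝ (degree + 1); with no planted core the edge count is exactly
`(attach_m − 1) + attach_m (n − attach_m)`. Default `attach_m = 3` (mean
degree ≈ 6, the sparse range of curated interactomes). The planted dense core
is a clique wired over the `planted_clique_size` highest-degree backbone
nodes. This placement is a deliberate modelling choice: in real interactomes
the innermost k-core coincides with the most-connected proteins, and a
design-phase power analysis showed a clique planted on uniformly random
(mostly peripheral) nodes has near-zero betweenness and is structurally
invisible to the four-median screen — it would emulate a different, and
unrealistic, topology. `planted_on="uniform"` retains the peripheral variant
for exactly that kind of negative experiment.

**Cohort.** Each patient draws a combined expression group from
`group_probs` (defaults 56/130, 54/130, 9/130, 11/130 for double-high,
double-low, A-high/B-low, A-low/B-high — the composition of a published
130-patient series). Marker staining is generated from a latent propensity
`t = μ(status) + irs_noise · u`, `μ_high = 2.0`, `μ_low = −1.5`, where `u`
mixes a shared per-patient factor with marker-specific noise; percentage
positive is `100·sigmoid(t)` (values < 0.5% read as 0) and intensity
`round(1.5 + 0.9 t)` clipped to 0–3. Consequences, all covered by tests:
high-status IRS stochastically dominates; the top-score atom stays below half
the cohort so the median split recovers true status for ~86% of patients
(~4.5% of 130-patient cohorts still land a degenerate median, handled as
above); the shared-factor weight `min(1, 1.32·spearman_target)` yields a
realised IRS Spearman of ≈ 0.67 at the default target 0.68 (the 1.32 gain,
calibrated once, offsets rank attenuation from IRS discretisation).
Categorical covariates (age band, gender, AFP status, T stage, grade, growth
pattern, cirrhosis, underlying liver disease) are drawn independently with
the margins of the same 130-patient series.

**Survival.** Event times are exponential — the simplest model whose hazard
ratio is well defined and recoverable without Cox fitting — with overall-
survival hazard `baseline_hazard` (default 0.012/month) times `hazard_ratio`
(default 5.829) for the double-high group; disease-free survival uses a 4/3
larger baseline and is truncated at death. With these defaults ~70% of a
cohort has an event within 60 months, matching the five-year outcome scale of
the reference series. Censoring is independent: with probability
`censor_prob` the observation is cut at a uniform fraction of the event time;
because the censoring fraction is equal in both groups, the rate-ratio HR
estimator `(events/exposure)_B / (events/exposure)_A` remains consistent
under this scheme (the per-group exposure deflation cancels), which the
bias-shrinks-with-n test verifies empirically.

What the generators do **not** emulate: real database content or identifier
messiness beyond a mapping table, confidence-weighted interactions,
hepatitis-etiology correlation structure between covariates and outcome,
non-constant hazards, or scheduled-visit (interval) censoring. Passing tests
therefore demonstrate correctness of the algorithms and calibration of the
statistics under the stated generative model, not biological validity on any
particular real dataset.

## Problem sizes and numerics

The test suite runs the oracle-equivalence battery on 100 random graphs of up
to 30 nodes (agreement to 1e−9), planted-core recovery on twenty 500-node
graphs (mean precision and recall ≥ 0.9), log-rank calibration on 2000 null
simulations of 30 + 30 patients, and HR recovery on 200 replicates of 1000
patients per group — sizes chosen so the full suite completes in about a
minute on one CPU while keeping Monte-Carlo standard errors well inside the
asserted tolerances. Ties are broken lexicographically everywhere; graph
outputs are byte-reproducible for a given seed, and the CLI manifest records
config, derived per-stage seeds, package version and input checksums.

## Known limitations

* Node/edge betweenness is exact (O(nm)); no sampling approximation is
  provided, so very large interactomes (≫10⁴ nodes) are out of intended
  scope.
* The candidate-stage core/edge-betweenness scope ("candidates" vs "full")
  is a genuine degree of freedom in published screens; both are implemented,
  defaulting to the candidate subnetwork.
* Cox proportional-hazards modelling is intentionally not re-implemented;
  the exponential rate-ratio estimator is the HR surrogate throughout.
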