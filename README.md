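# ppiscreen

Topology-based screening of candidate disease markers on protein–protein
interaction (PPI) networks, with the clinical-validation statistics used to
follow up a screened marker pair, and matched synthetic-data generators so the
whole pipeline runs end to end without any external database.

The package is aimed at systems-biology analysts who prioritise candidate
genes/proteins from interaction networks (e.g. hepatocellular-carcinoma marker
screens built from disease-gene compendia and PPI databases) and at anyone who
needs the downstream validation arithmetic — immunoreactive scores, median
dichotomization, contingency tests, Kaplan–Meier/log-rank survival comparison
— in one reproducible place.

## The method

Given a set of disease-significant proteins and a PPI network over the same
identifier namespace, the screen works on the marker-induced subgraph
*G = (V, E)*:

1. **Hubs.** A node *v* is a hub iff `deg(v) > 2 · median(deg)` over all nodes.
2. **Four-feature filter.** For every node the pipeline computes
   - degree `deg(v)`,
   - betweenness `B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st` (fraction of shortest *s–t*
     paths through *v*; normalised by `(n−1)(n−2)/2`),
   - closeness `C(v) = r_v / Σ_{u reachable} d(v,u)` with `r_v` the number of
     reachable nodes (so `C ≡ 1` on a clique and disconnected graphs are well
     defined),
   - coreness `K(v)`, the largest *k* such that *v* survives in the *k*-core
     (the maximal subgraph with all degrees ≥ *k*).
   A hub is a **candidate marker** iff it strictly exceeds the hub-set median
   of *all four* features.
3. **Crucial candidates.** On the candidate-induced subnetwork, k-core
   decomposition yields the innermost (main) core, and edge betweenness
   `B(e) = Σ_{s<t} σ_st(e)/σ_st` ranks interactions; the top-ranked edge is
   the **key interaction** bridging cores.

All graph measures are implemented from scratch (Brandes accumulation for
node/edge betweenness, BFS closeness, iterative-pruning coreness) on an
adjacency-set graph type, and are tested against independent brute-force path
enumeration and against networkx.

The clinical arm scores each tumor as
`IRS = percentage category (0–3) × intensity (0–3) ∈ {0,…,9}`, splits a cohort
at the median IRS (strictly above = "high"), and reports chi-square
associations with clinicopathological covariates, the Spearman correlation of
a marker pair, and Kaplan–Meier curves with log-rank tests per marker, for the
double-high group versus the rest, and across the four combined expression
groups. Under an exponential survival model the hazard ratio (HR) of two
groups is estimated by the rate ratio `(events/person-time)_B /
(events/person-time)_A`.

## Worked example

```bash
ppiscreen run-all --seed 11 --out-dir demo
```

simulates a 500-node scale-free PPI network with a planted 30-protein dense
core plus a 130-patient two-marker cohort, screens the network, and validates
the marker pair. The log prints:

```
INFO ppiscreen: simulate: 500 nodes, 1852 edges, 500 markers, 130 patients
INFO ppiscreen: screen: 75 hubs, 30 candidates, main core k=29
INFO ppiscreen: validate: n=130, spearman rho=0.686, OS 4-group log-rank p=2.098e-09
```

Reading: of 500 proteins, 75 pass the hub rule; exactly the 30 planted-core
proteins survive the four-median filter, and their subnetwork is a complete
core (k = 29). In the cohort, the two markers' IRS correlate at ρ = 0.69, and
overall survival differs strongly across the four combined expression groups
(the simulated double-high group carries a hazard ratio of 5.829). Artifacts
in `demo/`: `candidates.txt`, `hub_features.tsv`, `thresholds.tsv`,
`ranked_interactions.tsv`, `screen_report.json`, `validation_report.json`, and
a `manifest.json` capturing config, seeds and input checksums — re-running
with the same seed reproduces every file byte for byte.

The same stages are available as `ppiscreen simulate`, `ppiscreen screen
--markers … --ppi … [--id-map …]`, and `ppiscreen validate --cohort …` for use
on your own marker lists, edge lists and cohort tables (plain delimited text;
see the module docstrings in `src/ppiscreen/` for formats).

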