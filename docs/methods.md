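# Methods

## The procedure

`netprio` ranks candidate drug targets by combining a two-group
transcriptome comparison with a protein-protein interaction (PPI)
backdrop. The assumptions are those of the classic "central =
important" heuristic in network biology: differential expression marks
disease-relevant genes; among those, proteins that are topologically
central in the network of their mutual interactions are more likely to
be functionally consequential, hence better drug targets. The pipeline
makes each of those steps explicit and reproducible; it does not model
regulation mechanistically, and a protein can only surface if it is
both differentially expressed and present in the interactome.

## Differential expression

Input is an already-normalized log-scale genes × samples matrix with
case/control labels (normalization and probe-to-gene collapsing are out
of scope; matrices with missing values are rejected at load rather than
imputed). Two routes:

- **ANOVA route.** Per-gene one-way fixed-effects ANOVA across the two
  groups; with two groups F(1, n−2) equals the squared pooled-variance
  t statistic, a test-locked identity. Genes pass at raw p < α
  (default α = 0.05). Degenerate genes (zero within-group variance)
  yield p = 1 when the group means agree and the p → 0 limit when they
  differ; genes constant across *all* samples are never called and are
  counted in a warning.
- **Fisher route.** The contingency construction is not canonical, so
  this package adopts a *median split*: each gene is dichotomized at
  its overall median (ties fall in the "below-or-equal" cell) and the
  2×2 group × above/below table is tested with a two-sided Fisher exact
  test; p-values are Benjamini–Hochberg adjusted and genes pass at
  adjusted p < α. Users with their own per-gene tables can call
  `fisher_exact_two_sided` directly. The two-sided p sums the
  hypergeometric probabilities, over all tables with the observed
  margins, of tables whose probability does not exceed the observed
  one; a relative tolerance of 1e-7 on that comparison absorbs float
  noise between mathematically equal probabilities.

Direction (up/down) always comes from the sign of (case mean − control
mean), for both routes. Multi-platform designs are merged by taking
each gene's minimal raw p across platforms before thresholding.

BH adjustment is the step-up rule: sort ascending, multiply p_(i) by
m/i, enforce monotonicity by a cumulative minimum from the largest
rank, cap at 1.

## Interactome and QQPPI

PSI-MITAB 2.5 input is interpreted minimally: identifier columns 1/2
and alias columns 5/6, preferring aliases tagged `(gene name)`;
multiple database files are unioned with per-edge provenance. The graph
is keyed by gene symbol because the DEG and drug tables are
symbol-keyed; an optional identifier-map hook translates accessions,
dropping (and counting) unmapped records. Self-interactions are removed
— every centrality below assumes a simple graph.

The QQPPI (query-query PPI) network is the induced subgraph on the DEGs
present in the interactome: only direct interactions among queries.
Centralities are computed on its **largest connected component** (ties
broken toward the component containing the lexicographically smallest
symbol): closeness and centroid value are undefined across components,
and restricting all five measures to one component keeps the ranked
lists comparable. Nodes outside the component never enter the rankings;
their count is reported. Up/down annotations are carried through for
reporting and export only — they play no role in centrality or
selection.

## Centrality measures and numerics

All five measures are implemented directly (see README for the
formulas) with these conventions, chosen to match the mixed scales
conventionally reported (raw integer degree and centroid value,
normalized betweenness/closeness, unit-norm eigenvector):

- betweenness by Brandes' accumulation over all-pairs BFS, divided by
  (n−1)(n−2)/2; graphs with n < 3 return zeros with a warning;
- closeness as (n−1)/Σd on unweighted distances; disconnected input is
  an error (the caller passes the largest component);
- eigenvector by power iteration on A + I from the uniform positive
  vector, stopping when the max successive-iterate difference is below
  `tol` (default 1e-12, `max_iter` 10 000). The identity shift
  guarantees convergence on bipartite graphs, where ±λ_max otherwise
  tie; non-convergence raises with the residual.
- centroid value from the full γ table: γ_v(u) counts *all* nodes w
  with d(w,v) < d(w,u), endpoints included (d(v,v) = 0 always counts
  for v), ties for neither. The endpoint convention is deliberate and
  test-locked against a brute-force oracle using the identical
  definition, since prose definitions in the literature are ambiguous
  on this point. Values lie in [−(n−1), n−2].

Edge weights, if present in input, are ignored.

## Consensus selection

Top-k per measure (k default 30) with *all* ties at the k-th value
included, which makes selection independent of input order; eigenvector
values within 1e-12 absolute are treated as tied to avoid float-order
nondeterminism. A node is consensus-central with membership in at least
`min_measures` (default 2) of the five top lists. The rule is a plain
set intersection count — no weighted rank aggregation.

## Drug mapping

Consensus genes are joined against a TSV of (gene, drug_id, drug_name,
action, groups). Drug identity is the case-normalized drug *name*,
because curated tables repeat database accessions across target rows;
combination entries are kept verbatim as single drugs. Group filtering
keeps records whose development-group set intersects the allowed set
(default all of approved/experimental/investigational). A manual
literature-verification step has no computational counterpart here; an
optional user-supplied keep-list of drug names stands in for it. The
packaged fixture `data/table2_drug_targets.tsv` transcribes a curated
21-drug / 14-target table and is guarded by a checksum test.

## Synthetic studies

The generator emulates the statistical structure the pipeline assumes:

- **Interactome**: Barabási–Albert preferential attachment
  (`interactome_nodes` default 949, `attachment_edges` default 2,
  giving ~2 edges/node — the density regime of real query networks,
  ~1.9–2.6 edges/node). PPI networks are approximately scale-free; any
  connected generator with similar degree heterogeneity would serve.
  Node labels are zero-padded symbols (G0001, ...) so orderings are
  deterministic.
- **Hubs**: `n_planted_hubs` random nodes each gain exactly
  `extra_degree` new edges to random non-neighbors; other hubs are
  excluded as endpoints so the degree boost is exact. These are the
  recovery targets for the consensus rule.
- **Expression**: per-gene baseline ~ N(8, 1) on a log2-like scale,
  i.i.d. N(0, `noise_sd`) noise, and a ±`effect_size` case-group shift
  for the planted `deg_fraction` of genes, split 50/50 up/down.
  Defaults — 43 cases vs 24 controls, 2000 genes, 10% DEGs, shift 2,
  noise 1 — give essentially complete ANOVA power at α = 0.05, so
  recall failures indicate implementation defects, not sampling noise.
  At the pipeline level, planted hub genes are forced into the planted
  DEG set; otherwise hub recovery through the DE filter would be a
  coin flip and test nothing about the network stages.
- **Drugs**: each of `n_drugs` drugs targets 1–4 genes sampled with
  probability ∝ degree^`hub_bias` (default 2), mimicking the
  overrepresentation of well-studied hub proteins in curated drug
  databases; `hub_bias` = 0 is uniform.

One global seed governs everything through the fixed derivation rule
seed+0 (interactome), +1 (hubs), +2 (expression), +3 (drugs), so stages
can be regenerated independently. No stage reads the clock or OS
entropy; two runs with one config are byte-identical (fixed column
orders, fixed float formatting, no timestamps in the report).

What the generator does *not* emulate: probe-level microarray
structure, platform effects, correlated co-expression, non-Gaussian
noise, and the ascertainment biases of real interactomes (study bias,
false-positive interactions). Passing tests therefore demonstrate the
pipeline's correctness and calibration under its own assumptions, not
robustness to those real-data pathologies.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each property is sharply testable: oracle
equivalence on 20 random connected graphs with n = 25; exhaustive
Fisher enumeration for all 2×2 tables with total ≤ 24; type-I
calibration on 2000 null genes; hub recovery on 500-node graphs with 5
hubs boosted by 40 edges over 50 replicates (recovery of ≥ 4/5 hubs in
≥ 90% of replicates is the design target; measured rate is typically
100%).

## Known limitations

- Two-group designs only; the ANOVA generalizes to more groups
  mathematically but multi-group calling is not exercised.
- The median-split Fisher construction is one defensible choice among
  several; results for borderline genes depend on it.
- Consensus membership is binary per measure; near-misses at rank k+1
  carry no weight.
- Symbol-keyed joining silently merges distinct proteins that share a
  gene symbol and misses synonym mismatches unless an identifier map
  is supplied.
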