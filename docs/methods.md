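# Methods

## The interconnectivity statistic

Let `G = (V, E)` be a cleaned interactome and `Q` a query set of protein
symbols (de-duplicated, case-normalised).  With `M = Q ∩ V` the mapped
query and `G[M]` the induced subgraph (edges of `G` with both endpoints in
`M`), the interconnectivity is

```
f(Q) = |largest connected component of G[M]| / |M|
```

Components are found by iterative breadth-first search restricted to `M`.
The denominator is the *mapped* size, not the raw query size: query
members without interaction annotations carry no evidence about wiring
either way, and the published reference values for this statistic divide
by the annotated-protein count.  Degenerate cases are defined, not
errors: `|M| = 1` gives `f = 1` (a singleton is connected), `|M| = 0`
reports the fraction as missing.

### Cleaning rules

Raw interaction rows are filtered in a fixed rule order — non-physical
(genetic) interactions, off-species rows (either interactor outside the
requested taxon), self-loops, then duplicate unordered pairs — and each
removed row is counted against the first rule it violates, so the
provenance counts always sum to `rows − surviving edges`.  Duplicate
detection ignores evidence metadata: an edge either exists or not.
Proteins appearing only in removed rows are dropped rather than kept as
isolated nodes; the cleaned graph is meant to be the control network for
connectivity statistics, and isolated nodes can never join a component,
so keeping them would deflate every null fraction by a constant that
depends on bookkeeping rather than biology.

## The resampling null

The null for a query of mapped size `s` is plain uniform node sampling:
each replicate draws `s` distinct nodes from `V` without replacement and
evaluates `f`; the summary is the replicate mean and the unbiased
(`n − 1`) standard deviation, and an observed set is scored as
`z = (f_obs − mean) / sd` (no continuity correction; `z` is missing when
`sd = 0`, e.g. on a complete graph).  No degree matching is applied — the
question the statistic answers is "is this set more interconnected than a
random set of the same *size*", and the null curve makes the strong size
dependence explicit rather than hiding it.

Defaults follow the sampling conventions of the analysis this package
implements: 100 replicates per point for the expectation curve (grid from
50 nodes upward in steps of 50; smaller samples are excluded because their
fraction estimates are dominated by variance), 1000 replicates for
significance testing of an observed set.

Seeding: a master seed expands through `numpy` `SeedSequence` spawning
into one child per replicate (and one per curve point), so any point of a
curve can be recomputed independently and extending the grid or adding
replicates never perturbs earlier draws.  Pipeline stages derive their
seeds from `(master seed, CRC32 of the stage name)`, so adding a stage
leaves the others' randomness untouched.

### Calibration

When the query itself is a uniform random sample, its `z` should behave
like a standard normal score.  The acceptance suite verifies this on a
3000-node preferential-attachment graph with 100-node queries: the
empirical rate of `|z| > 1.96` over 500 trials must lie in `[0.02, 0.10]`
— a deliberately wide band, because `f` at small sizes is discrete
(multiples of `1/s`) and right-skewed, so the normal approximation is
serviceable rather than exact.

## Degree-distribution fit

`P(k)` is the raw count of nodes with degree exactly `k`.  The fit is
ordinary least squares of `log10 P(k)` on `log10 k` over all degrees
`k ≥ 1` with positive counts (degree-0 nodes are excluded — their log is
undefined — and noted in the log).  Reported quantities: coefficient
`a = 10^intercept`, exponent `b = slope`, `r²`, the degree range used and
the number of fitted points.  This is intentionally the network-viewer
regression, using raw counts and full support; it is a descriptive check
of heavy-tailed topology, not a maximum-likelihood tail estimator, and no
goodness-of-fit hypothesis test is attached.  Exact property: scaling all
counts by `c` multiplies `a` by `c` and leaves `b` unchanged.

## Overlap and enrichment statistics

Fisher-exact overlap tests always take an explicit background universe;
set members outside it are dropped with a logged count (mirroring
analyses restricted to identifiers present in both source databases), and
the default alternative is one-sided enrichment.  Gene-set enrichment is
the one-sided hypergeometric test per set with fold enrichment
`(k/n)/(K/N)`; `adjusted_p` is Benjamini–Hochberg step-up FDR, and the
high-confidence reporting view keeps rows with adjusted `p < 0.001` and
fold ≥ 2.  An EASE-style conservative toggle (scoring `k − 1` hits) is
available but never the default: its output is tied to a particular web
tool's database snapshot and is not comparable across universes.

## Cocktail fixtures

The package ships the ten published transgene-free reprogramming cocktail
compositions verbatim (including variant spellings, which the loader
canonicalises case-insensitively through a synonym catalog), the 22
non-redundant SMs with functional categories and main bioactivities, and
the 28 SMs found in the human metabolome.  Category assignment follows the
main bioactivity: HDAC/HMT/DNMT/LSD1/DOT1L inhibitors → epigenetic; GSK3
inhibitors → metabolic (they switch metabolism toward glycolysis);
TGFβ/cAMP/retinoic-acid/ROCK/MEK/p53 modulators → signaling.  BrdU is
annotated `{epigenetic, other}`: it is a thymidine analog that
incorporates into genomic DNA and perturbs chromatin, and it is the only
member of its cocktail that can supply the epigenetic arm — the reading
under which the published claim that every cocktail covers all three
categories holds.  Two internal inconsistencies of the source listings
are reproduced as computed, not patched: CHIR99021 appears in 8 of the 10
compositions (the prose says 7), and NaB in 2 (the prose implies 1).

## Synthetic data

The generators emulate the statistical structure the analysis assumes:

* `gen_scale_free(n, m, seed)` — preferential attachment (each new node
  attaches to `m` existing nodes with probability proportional to
  degree); connected, simple, heavy-tailed.  Default benchmark: `n = 3000`,
  `m = 2`, a size that keeps a full resampling study to seconds while
  leaving three orders of magnitude between typical and hub degrees.
* `gen_er(n, p, seed)` — Erdős–Rényi control of matched density.
* `gen_planted_target_map` — chemicals draw their targets from a *planted
  module* with probability `purity`, else uniformly from the rest.  The
  module is a dense node set of the existing graph, found by a
  deterministic greedy: start at the highest-degree node, repeatedly add
  the node with most edges into the current set (ties: higher degree,
  then lexicographically smaller symbol).  Choosing an existing dense set
  — rather than wiring in a synthetic clique — leaves the null graph's
  degree sequence untouched, so calibration runs on exactly the graph the
  planted signal lives in.  Defaults: module 100, 5 chemicals × 30
  targets, combined score 0.9 with experimental evidence only, so tables
  survive the standard channel/confidence filters (text-mining and
  prediction channels are zero and excluded by convention; the default
  confidence cut-off is the medium-stringency 0.4).
* `gen_overlap_universes` — compound universes with exact subset and
  overlap cardinalities for Fisher tests.

What the synthetic benchmark does *not* emulate: real interactomes'
study bias (hub degree correlates with research attention), edge noise
and literature redundancy, the mixture of direct/indirect chemical-target
evidence, or identifier ambiguity.  Passing tests therefore demonstrate
that the statistics are implemented correctly and are well calibrated
under their own assumptions — not that any particular biological target
set is significant.

## Problem sizes and tolerances

The test and acceptance workloads use a 3000-node interactome, 500
calibration trials, 100 planted/scattered seeds at 1000 null replicates
each, and 10,000 replicates for the two-clique closed form (expected mean
fraction `600/1225 · 1 + 625/1225 · 0.5 = 0.744898`, checked to ±0.02).
The power-law recovery uses the rounded `1000·k⁻²` histogram for
`k = 1..20` (half-up rounding), where OLS recovers the exponent to within
0.02 and r² ≈ 0.9985 (the residual is the integer rounding).  Exact
combinatorial quantities (cocktail counts, Fisher and BH closed forms)
are asserted exactly.

## Known limitations

* The BFS statistic and null run in pure Python over integer adjacency
  sets; a 20k-node interactome with thousands of replicates is minutes,
  not seconds.  The per-replicate seeding contract makes the loop
  trivially parallelisable if needed.
* The greedy planted module is a heuristic for a dense set, not the
  maximum-internal-degree subset (that problem is NP-hard).
* No degree-preserving rewiring null is provided; observed z-scores
  conflate "denser than random" with "hub-richer than random" by design.
* Chemical identifier namespaces are taken as given; no mapping service
  is consulted, and cross-database overlap tests require the caller to
  supply a consistent universe.
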