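# Methods

This note documents the models, procedures, parameter choices and known
limitations of `modessence`. It covers what the code computes and why the
defaults are what they are; every number quoted here is produced by the
test suite or `scripts/acceptance.py`, not asserted from elsewhere.

## Networks and provenance filters

Interaction tables are read as tab-delimited records `(protein_a,
protein_b, experimental system, source id, optional bait)`. Protein ids
are upper-cased systematic names; no alias resolution is attempted — the
synthetic generator controls its own namespace, and real-data users are
expected to supply systematic names. Records are symmetrized
(networks are undirected); bait/prey roles survive only as provenance.
Duplicate records collapse to one edge at graph build, with the
supporting `(system, source)` set kept per edge.

Three provenance filters are implemented:

* **Sticky-protein filter** (`max_per_source = 30`): if a protein has
  strictly more than 30 records from a single source, *all* of that
  protein's records from that source are removed (records from other
  sources are untouched). The threshold counts records per
  (protein, source), the most direct reading of "interactions from a
  single experimental data source"; counting unique partners instead is a
  one-line change but not exposed as an option.
* **Evidence classes**: *direct* admits Biochemical Activity, Co-crystal
  Structure, Far Western, FRET, Protein-peptide, Reconstituted Complex and
  Two-hybrid; *pulldown* admits Affinity Capture-Western and Affinity
  Capture-MS; *full* admits everything except Affinity Capture-RNA and
  Protein-RNA. The vocabularies are arguments with these defaults; system
  labels compare case-insensitively. Systems unknown to both lists fall
  only into *full*.
* **High-throughput restriction**: keep sources with ≥ 50 records and
  strictly more than 10 distinct baits (both bounds deliberately
  asymmetric: "at least 50", "more than 10").

All downstream analyses run on the subgraph induced by the
essentiality-tested protein universe.

## Module catalogs

Complex catalogs are TSV (`id<TAB>member,member,...`). Deduplication
removes strict-subset complexes, then for pairs with Jaccard index ≥ 0.5
removes the smaller (size ties: the lexicographically larger id), repeated
to a fixpoint in a deterministic order (descending size, then id), and
finally removes explicitly listed ribosomal complexes. The Jaccard cutoff
is a parameter; 0.5 is the conventional "more shared than not" cut, and
results should be read per threshold.

Process modules come from specific BP terms — by default terms annotating
between 5 and 50 proteins after true-path propagation. *Filtered*
processes additionally subtract complex contributions: for each process,
every complex (from the raw, pre-dedup catalog) sharing ≥ 2 proteins with
the process's full membership has the shared proteins removed; processes
left with < 2 members or with less than half their declared annotation
count are dropped, and the survivors are deduplicated like complexes. The
intersection trigger (2) is a parameter. Intersections are computed
against the process's original membership, which makes the subtraction
order-independent.

## Degree categorization

Given a module universe, an edge is *intramodular* when its endpoints
share a module, *intermodular* when both endpoints are annotated but share
none, and *unannotated* otherwise. Per-protein intra/inter degrees count
each edge once regardless of how many shared modules cover it. Because
proteins can sit in several modules, two complementary statistics address
multi-membership: the size of the protein's largest containing module
(ties broken to the lexicographically smallest id) together with the
partner count inside that single module, and that count divided by the
module size (the normalized intramodular degree; the denominator includes
the protein itself).

Hub-fraction curves sort proteins by non-increasing degree (ties broken by
protein id so output is deterministic) and admit them in cumulative groups
of 50 (modules: 20), reporting the essential fraction at each step; an
option extends group boundaries so tied degrees never straddle one, and a
final partial group is always reported.

## Semantic similarity

Term similarity is Lin's measure on annotation probabilities
`p(t) = term_count(t) / proteome_size` (propagated counts):
`tSS = 2 log p(a*) / (log p(t1) + log p(t2))`, where `a*` is the common
ancestor with minimum probability — the standard resolution of "a least
common ancestor" in a DAG. Identical terms score 1. When the most
informative common ancestor is an ontology root the score is 0
*structurally*, not merely when p(root) = 1: the reference proteome may be
larger than the annotated set (the default proteome is the
essentiality-tested universe), in which case p(root) < 1, yet a root-level
meeting point still carries no shared information. Ties between a root and
a non-root at the same probability prefer the non-root. The ratio of
logarithms makes the base immaterial (verified to 1e-12).

Protein similarity aggregates term similarity over propagated annotation
sets. The default scores
`pSS = 2 log p(s*) / (log p(m1) + log p(m2))` with `s*` the most
informative shared term and `m1`, `m2` each protein's own most informative
term; identical sets score 1, root-only sharing scores 0. A naive maximum
of `tSS` over all propagated term pairs would score 1 for *any* shared
annotation, which is why this aggregation was chosen. A best-match-average
over direct terms is available (`aggregation="best_match_average"`) and
labelled in output metadata. Unannotated proteins yield a missing value,
never 0. The semantic-similarity degree of a protein sums `pSS` over its
interactions; undefined pairs contribute 0 and are counted in a coverage
diagnostic.

## Rank statistics

Spearman and Mann-Whitney statistics are delegated to scipy behind this
package's interface; the test suite checks them against from-scratch
rank-Pearson, residual-correlation and exhaustive-enumeration oracles to
1e-10. Partial Spearman rank-transforms all three vectors (average ties)
and applies the first-order partial formula, with a t-approximation on
n − 3 degrees of freedom; a control correlation within 1e-12 of ±1 makes
the result undefined (flagged, not zero). The rank-sum test uses the exact
null for combined n ≤ 20 without ties, otherwise the tie-corrected normal
approximation. Because essentiality is binary, the SRCC against any degree
has a ceiling below 1; `max_attainable_srcc` computes it by rearranging
the labels onto the highest degree ranks (degree ties keep tied ranks, so
the value is arrangement-independent).

## Per-complex permutation test

A complex is testable when it has ≥ 2 essential and ≥ 2 non-essential
members, each with ≥ 1 intracomplex interaction; degrees are counted
within that complex only (this is what lets the test handle multi-complex
proteins). The statistic is the number of testable complexes where
essential members' mean within-complex degree strictly exceeds the
non-essential members' (ties count against). The default null shuffles
labels independently within each complex, preserving its essential count —
this conditions on complex composition and isolates the degree–label
association; a global pooled shuffle is available as an option for
sensitivity analysis. The
empirical p uses the (count + 1)/(n_perm + 1) correction and so is never
exactly 0 at the default 10,000 permutations. The within-complex null is
vectorized (one `argpartition` batch per complex), so 10,000 permutations
over tens of complexes take seconds.

## Cross-talk inference

For a module pair, cross-talk interactions are edges with one endpoint in
each module, excluding edges where either endpoint belongs to both
modules. The null model randomizes the intermodular edge set (edges whose
endpoints are both module members but share no module) by double-edge
swaps: per round, 10·|E| proposed swaps, each rejected if it would create
a self-loop, a duplicate edge, or an edge whose endpoints share any
module. This preserves exactly: every protein's intermodular degree,
every module membership, and the total intermodular edge count. The
proposal kernel (two uniformly drawn edges, random orientations) is
symmetric, so the chain's stationary distribution is uniform over the
reachable valid configurations; on a 4-edge toy instance with an
enumerable state space the sampled distribution over 10,000 rounds is
uniform by a chi-square check. With a fixed proposal count per round there
is no convergence failure mode — a round that accepts no swaps simply
returns the observed configuration, which is itself a valid state.

All pairs share the same 100 randomized networks; a pair's null mean is
its total randomized count divided by 100, *including* rounds where it
receives no edges. The odds-score is `(n_real + 1)/(n_rand_mean + 1)`; the
pseudocount damps pairs whose null means are near zero. A pair becomes a
cross-talk edge when its odds-score is at least the threshold (default
5.0, a parameter — the module-level relationship should be, and in the
synthetic study is, robust over a range of thresholds; raising the
threshold can only remove edges) *and* it has two vertex-disjoint
supporting interactions (equivalently, matching number ≥ 2).

The resulting module network carries per-module size, binary essentiality
(≥ 1 essential member), essential fraction, cross-talk degree (accepted
partners) and size-normalized degree. The essentiality analysis reports
SRCC of binary essentiality against degree, the partial SRCC controlling
module size, SRCC against normalized degree and against the essential
fraction, a Wilcoxon comparison of degree between essential and
non-essential modules, and a hub-module curve (groups of 20). Summary
counts (cross-talks, modules, essential fraction) are reported over
modules with at least one cross-talk, with the full node table available.
An optional functional-relatedness filter drops cross-talk edges between
modules that share a broad "slim" BP annotation: slim terms annotating
more than 500 proteins are ignored, and a module carries a term when at
least half its members are annotated with it (the fraction is a
parameter).

## Synthetic study design

The generator builds the statistical structure the analyses assume, at a
scale a single CPU handles in seconds:

* **2,000 proteins, 40 complexes of 10–30 members** (disjoint by default;
  an overlap knob exercises multi-membership code paths), intramodule edge
  probability **p_in = 0.3**, background intermodule probability
  **p_out = 0.005**. Background edges are drawn G(n, m)-style — a binomial
  edge count placed uniformly over eligible pairs — equivalent in
  distribution to per-pair Bernoulli draws for a simple graph and much
  faster than looping over ~2M pairs.
* **20 planted cross-talk pairs at p_crosstalk = 0.15**, drawn with
  probability 0.75 per endpoint from the essential modules, with at most
  two planted pairs per module. The cap keeps planted stubs dispersed: a
  module hosting many planted pairs would have so much intermodular degree
  that degree-preserving rewiring reproduces its pair counts and the
  enrichment becomes undetectable — with the cap, planted pairs score odds
  well above 5 and background pairs well below.
* **Essentiality**: 60% of modules are essential (comparable to the
  essential fraction among curated yeast complexes); within them
  P(essential) = logistic(−5 + 1.0 · intramodule degree), elsewhere a 5%
  base rate. The slope is deliberately sharp and centred near the mean
  intramodule degree (~5.7 at these sizes), so that essentiality is
  degree-driven *within* essential modules rather than a pure
  module-membership label; the overall essential fraction lands near the
  ~19% of systematic yeast deletion screens (18–20% across seeds).
* **Ontology**: one leaf BP-like term per module annotating exactly its
  members (≤ 50 by construction), grouped in fives under mid-level
  parents below a single root; written as OBO 1.2 / GAF 2.1 so the same
  parsers handle synthetic and real inputs.

All randomness flows through one `numpy.random.Generator` seeded from the
config; fixtures written twice from the same seed are byte-identical.
Structure generation uses integer draws and uniform comparisons only, so
results are stable across platforms for a given numpy stream.

**What the generator does not emulate**: scale-free degree distributions,
study/ascertainment bias, correlated experimental noise, protein
abundance effects, or overlapping process hierarchies. Passing tests
therefore demonstrate correctness of the machinery and sensitivity under
the planted model, not that real interactomes will show effects of the
same magnitude.

## Pipeline and reproducibility

`run_all` derives per-stage seeds from one top-level seed via
`numpy.random.SeedSequence`, runs network construction → catalog →
degrees/correlations → permutation test → cross-talk, and emits TSV
tables whose column layouts mirror the standard reporting format for the
per-complex test (n tested, n higher, empirical p) and the module network
(num cross-talks, num modules, fraction essential), plus a JSON manifest
(version, config echo, stage seeds). Reruns with identical config and
seed produce byte-identical outputs.

Default problem sizes — 2,000 proteins for the study, 10,000 permutations,
100 randomization rounds — run the whole pipeline in roughly ten seconds;
the unit suite uses smaller instances (hundreds of proteins, hundreds of
permutations) chosen so each oracle comparison stays exhaustive or
near-exact.

## Known limitations

* The protein-similarity aggregation implements the most-specific-shared
  form; other pSS aggregations exist in the literature, and the best-match-average
  alternative is provided for sensitivity analysis rather than as an
  equivalent.
* The sticky filter, Jaccard cutoff, intersection trigger, odds threshold
  and slim fraction are parameters with conventional defaults; analyses
  on real data should report sweeps over them.
* The rewiring chain's uniformity is verified on enumerable instances;
  on large networks uniformity over the constrained configuration space
  is the expected MCMC behavior, not something checked per run (the hard
  invariants — degrees, memberships, edge count, no intramodular edges —
  are asserted per round).
* Real-data ingestion (BioGRID tables, GO releases, complex catalogs) is
  format-compatible but not bundled; no retrieval code is included.
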