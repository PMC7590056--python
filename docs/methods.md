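# Methods

## Scope and data model

`ppinet` operates on an undirected simple graph over normalized gene
symbols (trimmed, upper-cased; no alias resolution — identifier unification
is left to the input column mapping). Edge lists are merged permissively:
taxon filtering keeps a record unless it carries a taxid different from the
filter, so rows without taxid columns always pass; self-pairs and unordered
duplicates are removed with counts reported. Node attributes carry the
number of supporting chemicals and source provenance; edge-level metadata
(interaction type, detection method) is dropped at build time because no
downstream stage consumes it. All outputs are sorted, so files are
bit-stable and the run manifest's SHA-256 hashes reproduce across reruns.

## Seed selection

Seeds are genes whose inference score strictly exceeds a threshold
(default 40; `strict=False` switches to ≥). Duplicate symbols in the score
table keep the maximum score. The strict comparison is deliberate: a
published threshold phrased as "scores > 40" excludes ties at the
threshold, and the choice is visible as a flag rather than buried.

## Connectivity significance

Two statistics quantify seed-gene localization:

* **LCC** — size of the largest connected component of the seed-induced
  subgraph; upper-tail test.
* **SHD** — mean over mapped seeds of the full-network shortest-path
  distance to the nearest *other* seed; lower-tail test. Seeds with no
  reachable co-seed are excluded from the mean and counted. This
  distance-to-nearest-neighbor form is a standard localization measure: a
  seed clique scores exactly 1.0, and tightly agglomerated disease genes
  score just above 1. An alternative (mean pairwise distance within the
  seed LCC) was considered and rejected as the default because it
  conflates module size with compactness. SHD is computed on the full
  interactome, not the extracted subnetwork, so that isolated seeds still
  contribute information through their network surroundings.

The null randomizes node *sets* (never edges): `n_reps` draws (default
1000) of exactly the mapped seed-list size, sampled without replacement,
uniformly by default. Uniform node nulls are known to be liberal on
heavy-tailed networks, so a degree-binned mode is provided that replaces
each seed with a node from the same log₂ degree bin (widening to adjacent
bins when a bin is exhausted). Replicate i draws from an RNG stream
derived from (seed, i), making the null vector independent of evaluation
order. Both statistics are evaluated on the same sampled sets.

Summaries: z = (observed − null mean)/null sd with the sample (n−1)
denominator — z is sensitive to this convention, hence documented;
empirical p = (r+1)/(n_reps+1), never exactly zero at finite replication.
A zero null sd flags z as undefined while the empirical p is still
reported. Calibration: under uniform sampling the empirical p of the
continuous-valued SHD statistic for a random set is approximately uniform
(checked by KS test in the suite); the LCC p is much more discrete (small
integer statistic with heavy ties) and its null distribution is uniform
only in the stochastically-conservative sense, so the calibration check is
run on SHD.

## MCODE

A from-scratch implementation of the three-stage molecular complex
detection algorithm:

1. **Weighting**: w(v) = k\*·density(H_{k\*}) with H_{k\*} the highest
   k-core of the *closed* neighborhood of v (the original definition);
   density uses the simple-graph formula.
2. **Prediction**: greedy growth from the heaviest unassigned vertex,
   admitting neighbors with w ≥ w(seed)·(1 − node_score_cutoff). The
   original description ("vertex weight percentage") is ambiguous between
   > and ≥; this implementation uses ≥, and the choice is unit-tested.
   Vertices already assigned to a complex are never revisited; growth is
   bounded by `max_depth` breadth-first levels.
3. **Post-processing**: complexes without a `k_core`-core (default 2) are
   discarded; fluff adds boundary vertices with closed-neighborhood
   density > 0.5 (fluffed vertices may appear in several complexes);
   haircut iteratively prunes degree-1 members. Haircut defaults to off —
   the tuned parameter set this package mirrors names fluff, k-core, score
   cutoff, and depth only.

Module score is density × size of the *pre-fluff* membership and drives
the M1…Mk ranking (ties broken by seed symbol); the pre-fluff membership
is retained on each module as `core_members`. Because fluff is by design a
liberal halo (it admits any dense boundary vertex, including degree-1
pendants whose closed neighborhood is trivially dense), recovery of
planted ground truth in the test suite is evaluated against the pre-fluff
cores where the study design contains such pendants; the halo is part of
the reported module membership regardless.

A consequence of the greedy growth worth knowing: two equally dense
complexes that share even one direct edge are merged into a single
complex, because each side's vertices pass the other's inclusion
threshold. This matches the reference plugin's behavior and is asserted in
the tests.

## Hub metrics

* Degree: distinct-neighbor count.
* Betweenness: unnormalized Brandes accumulation, endpoints excluded, each
  unordered pair counted once. Unnormalized values are the convention whose
  magnitudes match published hub tables (hundreds to thousands in a
  60-node module).
* MCC: Σ over maximal cliques containing v of (|C|−1)!, maximal cliques
  enumerated exactly by pivoting Bron–Kerbosch. Arithmetic is exact Python
  integers — real modules produce values beyond 10¹³ — with a scientific
  display column above 10⁶ alongside the lossless integer. An isolated
  vertex scores 0; on triangle-free graphs MCC equals degree (every edge
  is a maximal clique).
* MNC: largest connected component of the *open* neighborhood (the
  CytoHubba convention); 0 for isolated vertices.

Hub tables default to module-induced subgraphs (a flag computes them on
the whole network instead): published per-module hub values are consistent
with module-level computation, and the package makes the scope explicit.

## Overrepresentation and prioritization

Overlap significance is the hypergeometric upper tail P[X ≥ k]
(`phyper(k−1, lower.tail=FALSE)` semantics — the off-by-one is
unit-tested), identical to the one-sided Fisher exact p; the odds ratio
reported is the sample estimate ad/bc with infinity flagged when bc = 0.
BH-FDR is applied within each gene-set collection. The background universe
defaults to the interactome node set and is an explicit parameter — it is
the single most result-sensitive free choice in this kind of analysis.
Prioritization keeps modules with raw p < α in every required collection
(the "significant in all evidence sets" rule) and ranks them by summed
−log₁₀ of each collection's best p; raw rather than adjusted p is used
for the rule itself, with adjusted values reported everywhere.

## Synthetic data

The generator emulates the statistical shape of a disease-gene network
study: a background network (preferential attachment by default, because
real interactomes are heavy-tailed and uniform-null behavior depends on
the degree distribution; Erdős–Rényi mode for analytically transparent
tests), planted dense blocks wired internally with Bernoulli(p_within),
seed genes drawn as a stated fraction from the blocks with the remainder
uniform over the background, inference scores drawn uniformly from ranges
on either side of the selection threshold, and gene sets with exact
planted overlaps to chosen blocks. Ground truth is written as JSON and
consumed only by tests, never by the pipeline.

Blocks connect to the background with Bernoulli(p_between) but are
pairwise non-adjacent: a single direct edge between two equally dense
blocks would make MCODE merge them (see above), so inter-block
connectivity is routed through background paths. This keeps planted truth
recoverable while the seed-induced subnetwork remains connected through
background seeds.

The desk-scale "paper-like" default is one fixed study condition: 3000
genes, BA(m=3) background, four blocks of 60/65/70/74 members at
within-density 0.9 (dense blocks are the regime where MCODE's weight
threshold retains whole complexes), p_between = 0.004 (large enough that
the subnetwork spans all blocks through background seeds, small enough
not to blur the blocks), 300 seed genes with 70% drawn from blocks,
scores in (40.5, 100) against 700 decoys in (1, 39.5), and three evidence
sets of 120/150/200 genes overlapping blocks 0 and 1 by 25–35 genes each.
With 70% seed coverage, ~30% of each block is invisible to the pipeline by
construction; recovery is therefore scored against block ∩ subnetwork.

What the generator does **not** emulate: literature-curation bias in
gene–disease scores, correlated annotation errors between evidence sets,
protein-complex overlap (blocks are disjoint), and database-version drift.
Passing tests therefore demonstrate that the pipeline recovers structure
of this planted form at these signal strengths — not that any particular
real-data headline number will reproduce.

## Numerical and problem-size choices

Exact tests are computed by `scipy.stats.hypergeom` (log-space internally)
and clamped to (0, 1]; MCC uses arbitrary-precision integers; all
tie-breaks are lexicographic on gene symbol; degenerate inputs (empty
selections, unmappable genes, zero null sd, seeds with no reachable
co-seed) are reported, not silently absorbed. Test problem sizes were
chosen as the smallest at which each property is cleanly visible: oracle
equivalence on ≤12-node graphs (exhaustive enumeration), null calibration
on ER(200, 0.02) with 200 trials × 199 replicates, planted-clique
detection on a 1000-node background, MCODE recovery on 20 replicates of
800-node graphs, and the full pipeline on the 3000-node paper-like
condition with 1000-replicate nulls.

## Known limitations

* No identifier mapping: symbols that differ only by alias are distinct
  nodes.
* The uniform null does not control for degree; the degree-binned mode
  mitigates but does not equal a degree-preserving rewiring null (edge
  rewiring is deliberately out of scope — the method randomizes node
  sets).
* MCODE results can drift from specific plugin builds in tie-handling;
  determinism here is guaranteed by lexicographic tie-breaks, not by
  matching any particular binary.
* MCC enumeration is exponential in the worst case; it is intended for
  module-sized graphs (tens of nodes), not the full interactome.
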