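# Methods

## Problem and data model

`ppiclass` works on a simple undirected protein interaction network:
nodes are opaque protein identifiers, edges are physical interactions.
Self-loops are dropped and duplicate reports of an unordered pair are
collapsed, keeping the union of detection-method MI codes (the raw vs
non-redundant distinction is preserved in the load summary, which always
satisfies raw = nonredundant + duplicates + self-loops).  PSI-MI TAB
input uses columns 1–2 for interactor ids (first identifier, with or
without a `db:` prefix — exports vary) and column 7 for the
detection-method code.  Node identifiers are opaque; isoform selection
and id mapping are input preparation, outside this package.

Each interaction is described by 82 features in a fixed order:
7 sequence, 71 network, 4 functional-similarity columns.  Partner "A"
of a pair is always the lexicographically smaller identifier, so
feature vectors do not depend on the orientation in which an edge was
written; training and prediction must share this convention, which the
package applies automatically.

## Edge graphlet degree vectors

Graphlets are connected induced subgraphs on 2–5 nodes; there are
30 of them (1, 2, 6, 21 per size).  The edges of a graphlet fall into
*edge orbits* — equivalence classes under the automorphism group — and
there are 69 orbits in total.  The catalog is built by brute force,
which is exact and cheap at this size: all 2^C(k,2) labeled graphs per
size are canonicalized by the minimum adjacency code over all node
permutations, and orbits are computed by direct automorphism
enumeration.  No external isomorphism machinery is needed.

Global orbit ids order graphlets by (size, edge count, canonical code)
and orbits within a graphlet by smallest member edge.  This pins orbit
0 to the bare 2-node edge and orbit 68 to the 5-clique orbit, and — by
construction rather than design — also places the 3-clique and 4-clique
orbits at ids 2 and 12.  Ids of other orbits are a convention of this
package; the full catalog (adjacency lists plus orbit map) can be
exported as JSON (`ppiclass catalog`) for relabeling against any other
published numbering.

The EGDV of an edge e counts, per orbit, the graphlet occurrences
containing e.  Occurrences are enumerated as node *subsets* (so each
induced subgraph is counted exactly once) by neighborhood expansion in
the FANMOD/ESU style, seeded with e's two endpoints: the extension set
holds nodes adjacent to the current subset but outside its closed
neighborhood, which makes every connected superset reachable by exactly
one branch.  An independent exhaustive-subset counter
(`count_edge_orbits_bruteforce`) serves as the oracle in tests; the two
agree on hundreds of seeded random graphs.

Orbit 0 is touched exactly once by every existing edge and is excluded
from the 68-entry feature vector.  Raw counts span orders of magnitude,
so they are transformed as v = ln(1 + x) — the +1 keeps zero counts
defined — and then normalized by the vector sum (log first, then
normalize; an all-zero vector stays zero).

A known arithmetic subtlety: for an edge of K₁₀ the clique-orbit counts
are C(8,1)=8, C(8,2)=28, C(8,3)=56 (the two endpoints are fixed), and
the aggregated sub-clique totals are 120/210/252.  The brute-force
oracle confirms the per-edge binomials.

## Other network features

- **Edge degree**: number of edges sharing an endpoint with e, i.e.
  deg(u)+deg(v)−2 in a simple graph.
- **Edge betweenness**: unnormalized count of unordered node pairs
  whose shortest paths traverse e, with equal fractional splitting
  across tied paths (Brandes accumulation via networkx).  A pair
  contributes to its own connecting edge, so an isolated edge scores 1.
  The classic conservation identity (total betweenness = total
  shortest-path length over pairs) is asserted in tests.
- **PageRank affinity (APR)**: closeness of the two endpoints under
  personalized PageRank.  The exact variant used in prior work is not
  recoverable, so the package fixes a reproducible definition —
  personalized PageRank seeded at u and at v with damping 0.85 (restart
  probability 0.15), combined symmetrically as min(pr_u(v), pr_v(u)) —
  and exposes damping and the combination rule (min / product / mean)
  as configuration.  Intra-cluster edges score high because random
  walks from either endpoint revisit the shared cluster.

## Sequence features

ELM motifs are regular expressions; a protein's count is the number of
match *start positions* summed over all motifs, with overlapping
matches counted via lookahead scanning ("all occurrences", not the
regex engine's non-overlapping default).  Disordered binding regions
are ingested as 1-based inclusive intervals from external predictions;
touching or overlapping intervals are merged before computing the
region count, disordered-residue fraction, and longest-region length
(MaxDisLen takes the longer of the two partners).  A protein missing
from the FASTA is a hard error (motif counts need the sequence); a
protein missing from the disorder table legitimately has zero regions
and is summarized as (0, 0, 0) with a log note.

## Functional similarity

Wang-method term similarity: each ancestor t of a term A carries
S_A(t), the maximal product of edge weights along a path from A up to t
(S_A(A)=1), computed by relaxation in topological order over the
ancestor closure; SV(A)=Σ S_A(t), and
sim(A,B) = Σ_{shared t}(S_A(t)+S_B(t)) / (SV(A)+SV(B)).  Edge weights
default to the method's standard 0.8 (is_a) and 0.6 (part_of);
regulates-type relations are ignored.  Pair similarity per aspect is
the best-match average of the i×j cross-similarity matrix; MeanSim
averages the defined aspects.  A protein with no annotation in an
aspect yields NaN for that aspect — *unknown*, deliberately not 0
(*dissimilar*) — and the aspect is excluded from MeanSim.  Evidence
codes are not filtered by default (an optional filter exists).

## Classifier

`InteractionTypeClassifier` is a scikit-learn estimator wrapping a
10-tree random forest.  Training first applies plain random
undersampling: the minority class is kept whole and the majority class
is downsampled without replacement until the minority fraction reaches
`rus_ratio` (defaults 0.37 obligate/non-obligate, 0.31 SP/ME, matching
a 280-vs-493-scale imbalance).  The boosting component of
RUSBoost-style schemes is intentionally not reproduced; the ratio
semantics (post-sampling minority share) are the package's documented
reading of an underspecified parameter.  Missing features are imputed
with medians fitted on the undersampled training rows only.

Confidence is the fraction of trees voting for the winning class —
with 10 trees a multiple of 0.1, the two classes summing to 1 — rather
than averaged leaf probabilities.  A 5/5 vote is flagged indecisive and
excluded from downstream tallies.  Cutoff filtering keeps rows with
confidence ≥ the cutoff (0.6 by default, guaranteeing a 0.2 vote
margin); counts are reported per class and per four-way combination.

Evaluation is stratified k-fold cross-validation (k=10 default, seeded,
shuffled) with out-of-fold vote fractions pooled before computing
auROC (midrank ties), per-class F-measure at majority vote, and
precision per confidence cutoff on the grid 0.50–1.00 in steps of
0.05.  Feature ranking uses the two-sided Mann–Whitney U test per
column with per-class means reported; constant columns get p = 1 and a
flag.  Both tasks are trained on the full 82-column matrix.

## Complex analysis

Complexes are kept when they have ≥ 4 members and their members induce
a connected subgraph of the interaction network.  P(t,c) is the
frequency of the four type combinations among *decisive* classified
intra-complex interactions (indecisive and unclassified edges are
excluded from the denominator).  H(c) is the Shannon entropy in bits
and R(c) = 2 − H(c).  Enrichment: a complex is enriched in a type
reaching at least 50% of its classified interactions; at exactly 50%
two types can tie and both are flagged (each counted once per type in
dataset-level fractions).  Inter- vs intra-complex: an edge whose
endpoints share at least one complex is intra (for every such complex,
also under overlap); endpoints in different complexes only make it
inter.  Interaction-level GO annotation is the raw intersection of the
two partners' term sets (no ancestor closure by default); enriched-term
p-value machinery is left to external tools.

## Synthetic data

The generators emulate every input format with planted ground truth:

- **Networks**: Erdős–Rényi background (default 60 nodes, edge
  probability 0.05) with planted cliques (default one 6-clique), hub
  stars (default degree 12) and clique pairs joined by a single bridge
  edge (default two 8-cliques); the manifest lists each structure's
  edges.  Defaults are sized so planted topology dominates the
  background signal while brute-force verification stays instant.
- **Sequences**: background drawn from an alphabet disjoint from the
  motif's letters, so planted motif counts are exact; every sequence is
  re-scanned post hoc.  Disorder intervals and toy three-aspect tree
  ontologies (depth 4, branching 2) with annotation sets at controlled
  distances are emitted in the package's own file formats and are
  round-tripped through its readers in tests.
- **Labeled feature tables**: class-conditional draws whose means for
  the informative features follow the reported per-class means of real
  interaction types (e.g. disorder-region counts 2.17 vs 7.27 and mean
  functional similarity 0.816 vs 0.63 for obligate vs non-obligate;
  edge degree 36.6 vs 86.9 for SP vs ME), with class sizes 280/493 and
  933/3680.  Counts are Poisson, bounded quantities truncated
  Gaussians; only class means are published, so the variances are
  package presets chosen to keep class overlap realistic but
  separable.  The `null` preset draws both classes from pooled means.

What passing on synthetic data does **not** show: real interaction
features are correlated (degree with betweenness, orbits with each
other), label noise exists, and class-conditional distributions are
heavy-tailed rather than Gaussian/Poisson.  The synthetic results
validate the machinery (undersampling, vote fractions, CV, ranking),
not biological performance.

## Numerical choices and edge cases

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); rerunning any command with the same
  config is byte-identical in its primary outputs.
- Undersampling target: majority size = ceil(n_min(1−ratio)/ratio);
  a ratio already met is a no-op.
- EGDV of an edge with no 3+-node context is all zeros and stays all
  zeros after normalization.
- Betweenness and APR are whole-graph quantities; the feature assembler
  computes betweenness once per network and caches per-protein ELM
  counts.
- Ties at the confidence cutoff are kept (≥ comparison).
- Orbit lookups memoize on the labeled adjacency code of the induced
  subgraph plus the edge position, so repeated subgraph shapes cost a
  dictionary hit.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: orbit
oracle comparisons use 200 random graphs on ≤ 12 nodes (exhaustive
enumeration is exact there), classifier checks use the default
synthetic class sizes (hundreds of rows, 82 columns), and the null
calibration averages 10-fold CV over 20 seeds.

## Known limitations

- The exact published orbit numbering beyond ids 0, 2, 12, 68 is not
  guaranteed; use the exported catalog to map ids.
- The APR variant is a fixed, documented choice among several
  reasonable ones.
- No sampling-based approximate graphlet counting: dense hubs in very
  large networks make exhaustive per-edge enumeration expensive
  (5-node subsets grow as degree³).
- Training labels are inputs; deriving them (structure-based
  classification, interface-overlap analysis) is out of scope.
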