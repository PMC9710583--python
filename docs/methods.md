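# Methods

## Model

A compound–protein interaction network is a bipartite graph G = (C ∪ P, E)
with compounds C, proteins P and undirected scored edges E ⊆ C × P. A
biclique (C′, P′) is complete (every cross pair is an edge) and *maximal*
when no strict superset on either side preserves completeness. Maximal
bicliques of a bipartite graph coincide with the formal concepts of the
adjacency relation — pairs of sets that are each other's exact common
neighborhoods — so enumeration is implemented as Close-by-One (CbO)
closure search over the protein side with the canonicity test that
guarantees each concept is visited exactly once. Any correct enumeration
algorithm is acceptable; the test suite pins the behavior to an exhaustive
subset-enumeration oracle on 8×8 graphs across three edge densities, which
is the actual contract.

Prediction is biclique extension. For each maximal biclique (C′, P′) with
|C′| ≥ c_min and |P′| ≥ p_min:

* one-edge rule — a compound x ∉ C′ adjacent to exactly |P′| − 1 proteins
  of P′ yields a prediction for the single missing edge; symmetrically for
  proteins;
* two-edge rule (optional) — a candidate missing exactly two edges to the
  side it would join yields both, provided that side has at least
  `two_edge_min_side` nodes (default 4).

A candidate missing one edge to a side of size ≥ 2 is necessarily adjacent
to at least one biclique member, so restricting candidates to the
biclique's direct neighborhood is implied and not implemented as a
separate pass. Predictions derivable from several bicliques are one record
with aggregated support; when both one- and two-edge derivations produce
the same edge, the reported multiplicity is the minimum (1). Existing
edges are never re-predicted.

The size threshold (c_min, p_min) is the method's main dial: larger
bicliques give extensions more support (higher precision, lower FPR) but
exist in smaller numbers (lower recall). Sensible values run from (2, 2)
for sparse networks to around (5, 2) for denser ones; both sides are
bounded below by 2 since a biclique needs at least two nodes per side to
be informative.

## Cleanup filters

Applied before biclique analysis, all pure per-node predicates (hence
order-independent and idempotent):

* compounds with a known heavy-atom count < 5 are removed (ions and other
  tiny species interact unspecifically). Heavy atoms are counted from
  SMILES with RDKit; an unparseable or missing SMILES leaves the compound
  in place — removal requires positive evidence of small size;
* compounds flagged antibiotic, hormone/transmitter or steroid are removed
  (non-metabolic), as are compounds carrying only a KEGG drug ('D') number
  or no KEGG mapping; a 'D' number alongside a 'C' number is retained;
* degree-1 nodes cannot belong to any biclique with ≥ 2 nodes per side and
  are pruned. The default is a single simultaneous pass; a fixpoint mode
  (repeat until no degree-1 node remains) is available by flag. Published
  node accounts of this preprocessing step do not disambiguate the two,
  so neither is asserted as canonical.

Confidence filtering on score channels is inclusive (score ≥ threshold
retained); integer 0–1000 scores from link-table inputs are normalized
by 1/1000. Networks always drop isolated nodes, so node counts refer to
nodes with at least one interaction.

## Validation

`holdout_split` removes round(fraction·|E|) uniformly sampled edges
(round half away from zero; the rounding rule is a package choice since
"5%/10%" alone does not fix one). Removal does not re-trigger degree-1
pruning, so some positives may be unrecoverable — they still count in P,
matching the predictable-pair definition (both endpoints present in the
training network). Negatives that appear as edges of the input network are
excluded from N: a pair cannot be both a reported interaction and a
verified non-interaction; this also covers the held-out positives, which
by construction are input edges. Rates follow the standard definitions
TPR = TP/P, FPR = FP/N, F1 = 2TP/(2TP+FP+FN), PPV = TP/(TP+FP), plus the
confirmation rate TP/n_predicted, an estimate of expected experimental
validation success. Predictions matching neither validation set have
unknown status and count only toward n_predicted.

The threshold sweep scores all thresholds on the same split per repeat
(lower between-threshold variance; whether to re-split per threshold was
an open choice) and enumerates maximal bicliques once per repeat at the
loosest threshold, re-filtering per threshold — valid because maximality
does not depend on the threshold, and verified against per-threshold
recomputation in the tests.

## Null model

`edge_switch_randomize` runs the switching chain: propose two random
edges (c1,p1), (c2,p2); if the four endpoints are distinct and neither
(c1,p2) nor (c2,p1) exists, swap. Degrees on both sides, edge count,
bipartiteness and edge uniqueness are invariants of every step. Rejected
proposals count as attempts (Markov-chain semantics), bounding runtime.
The default number of attempts is ceil(|E|·ln(1/ε)) with ε = 1e-3
(≈ 6.9·|E|), the standard mixing heuristic for switching chains; it is a
flag because no universally agreed bound exists.

## Characterization

Compound similarity is the Tanimoto index |A∩B|/|A∪B| over hashed
circular substructure features (Morgan radius 2, sparse count keys),
with the convention 0 for two empty fingerprints. The fingerprint is a
package choice — published effect sizes depend on the feature set used,
so cross-fingerprint agreement is not asserted. Protein similarity is the
best local-alignment score under BLOSUM62 with affine gaps (open 11,
extend 1 — standard protein-search defaults), computed with Biopython's
PairwiseAligner and checked against an independent Gotoh dynamic program.
Scores are raw alignment scores, not E-values.

`within_between_similarity` samples, without replacement and excluding
self-pairs, n pairs sharing at least one biclique and n pairs sharing
none (with/without replacement was an open choice), and reports Cohen's d
with pooled standard deviation (NaN when the pooled SD is 0) and a
two-sided rank-sum p-value — exact when both groups are tie-free and
smaller than 50, otherwise the normal approximation with tie correction.

Pathway enrichment is the hypergeometric upper tail P(X ≥ k) for k
annotated query members out of n, against K of N in the universe
(default: all annotated proteins), with Benjamini–Hochberg adjustment
across tested pathways; rows with adjusted p below alpha (default 0.01)
are returned by descending fold enrichment (k/n)/(K/N).

## Synthetic benchmark

`generate` plants node-disjoint complete bicliques (defaults: six
bicliques of 4–6 compounds × 3–4 proteins in a 50×80 node budget — the
small compound-heavy shapes typical of curated CPI networks), adds
background edges outside the planted blocks with probability 0.02 per
pair (sparse-network regime; the heavy-tail mode scales per-compound
probabilities by Pareto(α=2) propensities to mimic currency metabolites),
removes a fixed number of edges per planted biclique as recoverable
ground truth, and samples negatives uniformly from the remaining
non-edges. All synthetic edge scores are 1.0; no attempt is made to mimic
a database's confidence-score distribution. Everything is a deterministic
function of the spec's seed.

Guarantee: with zero background noise and one removed edge per biclique,
extension at threshold (c−1, p−1) recovers exactly the removed edge of a
planted c×p biclique — the damaged block's two maximal bicliques
((C\{c*})×P and C×(P\{p*})) each regenerate it, and no other candidate
reaches |side|−1 adjacency. Since thresholds are floored at 2 per side,
the per-biclique threshold used in practice is (max(c−1,2), max(p−1,2)).
Passing tests on this generator demonstrate correctness of the machinery
and the direction of the null-model contrast; they do not certify
performance numbers on real networks, whose confidence-score noise,
identifier redundancy and correlated annotation structure the generator
does not emulate.

## Numerical and design notes

* All stochastic operations take explicit integer seeds (numpy
  `default_rng`); identical seeds give bit-identical outputs, and the CLI
  records seeds plus input SHA-256 digests in a run manifest.
* Iterative extension uses batch semantics (all predictions computed
  against the iteration-start network, then inserted together), which
  makes the result independent of node order; it stops when new
  predictions fall below `stop_new_below` (default 1 = strict
  convergence) or at `max_iter` (default 50). Density is monotone
  non-decreasing since edges are only added between existing nodes.
* Duplicate edge rows collapse keeping the maximum score per channel.
* The two-edge gate compares the candidate's *corresponding* side only
  (the side it would join); whether the opposite side should also be
  constrained is ambiguous in practice, and only the corresponding side
  is constrained here.
* The benchmark problem sizes used in the acceptance script (20 noise-free
  networks, 10 noisy networks × 10 hold-out repeats, 8×8 oracle graphs)
  were chosen as the smallest sizes at which the studied effects are
  stable across seeds.

## Known limitations

* Enumeration is exact and intended for desk-scale networks (up to
  ~10^5 edges); there is no approximate or streaming mode.
* Predictions are unweighted: edge confidence scores gate network
  construction but do not rank predictions, so no ROC over a continuous
  score is produced.
* No chemistry beyond heavy-atom counting and fingerprints — no salt or
  tautomer normalization; identifier merging of compound variants is
  delegated to a user-supplied equivalence mapping.
* Pathway enrichment supports flat pathway maps only (no ontology
  hierarchy).
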