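"""Synthetic bipartite CPI networks with planted bicliques.

Real compound-protein networks are sparse, have heavy-tailed compound
degree distributions (a few cofactor-like "currency metabolites" touch
many proteins), and contain dense complete bipartite patches (groups of
compounds binding the same protein set). The generator emulates exactly
those features: it plants node-disjoint complete bicliques, sprinkles
background edges (optionally with power-law compound propensities), and
removes a known number of edges from each planted biclique. The removed
edges form recoverable ground truth: with no background noise and one
removal per biclique, the extension rule at threshold (c-1, p-1) provably
recovers every removed edge and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bicliques import Biclique, SizeThreshold, predict, prediction_edges
from .evaluation import restrict_to_predictable, score_predictions
from .network import BipartiteCPINetwork, CompoundRecord, ProteinRecord

Pair = tuple[str, str]

#: Default planted-biclique shapes: a mix of the small, compound-heavy
#: bicliques typical of curated CPI networks.
DEFAULT_PLANTED: tuple[tuple[int, int], ...] = ((5, 3), (4, 4), (6, 3), (5, 4), (4, 3), (6, 4))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic network.

    ``planted`` lists (c_i, p_i) biclique sizes drawn on disjoint node
    sets; ``background_edge_prob`` is the per-pair probability of a noise
    edge between pairs not inside one planted biclique; ``heavy_tail``
    draws per-compound propensities from a power law to mimic currency
    metabolites.
    """

    n_compounds: int = 50
    n_proteins: int = 80
    planted: tuple[tuple[int, int], ...] = DEFAULT_PLANTED
    background_edge_prob: float = 0.02
    holdout_per_biclique: int = 1
    degree_model: str = "uniform"
    n_negatives: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.degree_model not in ("uniform", "heavy_tail"):
            raise ValueError("degree_model must be 'uniform' or 'heavy_tail'")
        if not (0.0 <= self.background_edge_prob < 1.0):
            raise ValueError("background_edge_prob must be in [0, 1)")
        if self.holdout_per_biclique < 0:
            raise ValueError("holdout_per_biclique must be >= 0")
        if sum(c for c, _ in self.planted) > self.n_compounds:
            raise ValueError("planted bicliques need more compounds than the node budget")
        if sum(p for _, p in self.planted) > self.n_proteins:
            raise ValueError("planted bicliques need more proteins than the node budget")
        for c, p in self.planted:
            if c < 2 or p < 2:
                raise ValueError("planted bicliques need at least 2 nodes per side")
            if self.holdout_per_biclique >= c * p:
                raise ValueError("holdout would empty a planted biclique")


@dataclass
class SyntheticTruth:
    """A generated network plus its recoverable ground truth."""

    network: BipartiteCPINetwork
    removed_edges: set[Pair]
    planted_bicliques: list[Biclique]
    negatives: set[Pair]


def generate(spec: SyntheticSpec) -> SyntheticTruth:
    """Generate a planted-biclique network; fully determined by spec.seed."""
    rng = np.random.default_rng(spec.seed)
    compounds = [f"c{i:04d}" for i in range(spec.n_compounds)]
    proteins = [f"p{i:04d}" for i in range(spec.n_proteins)]

    planted_bicliques: list[Biclique] = []
    planted_pairs: set[Pair] = set()
    ci = pi = 0
    for c_size, p_size in spec.planted:
        cset = compounds[ci: ci + c_size]
        pset = proteins[pi: pi + p_size]
        ci += c_size
        pi += p_size
        planted_bicliques.append(Biclique(frozenset(cset), frozenset(pset)))
        planted_pairs.update((c, p) for c in cset for p in pset)

    edges: set[Pair] = set(planted_pairs)

    # background noise among pairs outside every planted biclique
    if spec.background_edge_prob > 0:
        if spec.degree_model == "heavy_tail":
            w = rng.pareto(2.0, size=spec.n_compounds) + 1.0
            w = w / w.mean()
        else:
            w = np.ones(spec.n_compounds)
        probs = np.minimum(spec.background_edge_prob * w, 0.95)
        draws = rng.random((spec.n_compounds, spec.n_proteins))
        for i, c in enumerate(compounds):
            for j, p in enumerate(proteins):
                if (c, p) not in planted_pairs and draws[i, j] < probs[i]:
                    edges.add((c, p))

    # remove hold-out edges from each planted biclique (ground truth)
    removed: set[Pair] = set()
    if spec.holdout_per_biclique:
        for b in planted_bicliques:
            members = sorted((c, p) for c in b.compound_set for p in b.protein_set)
            idx = rng.choice(len(members), size=spec.holdout_per_biclique, replace=False)
            for i in idx:
                removed.add(members[i])
        edges -= removed

    # negatives: pairs never planted, never background, never removed
    non_edges = [
        (c, p)
        for c in compounds
        for p in proteins
        if (c, p) not in edges and (c, p) not in removed
    ]
    if spec.n_negatives > len(non_edges):
        raise ValueError("not enough non-edges to sample the requested negatives")
    neg_idx = rng.choice(len(non_edges), size=spec.n_negatives, replace=False)
    negatives = {non_edges[i] for i in neg_idx}

    # keep every node (even isolated) out of the record lists? The network
    # model drops nothing at construction; isolated nodes are legitimate
    # here and are pruned by restrict_to_predictable where it matters.
    used = {c for c, _ in edges} | {p for _, p in edges}
    net = BipartiteCPINetwork(
        [CompoundRecord(id=c) for c in compounds if c in used],
        [ProteinRecord(id=p) for p in proteins if p in used],
        {e: {"experimental": 1.0} for e in sorted(edges)},
        provenance=f"synthetic seed={spec.seed}",
    )
    return SyntheticTruth(
        network=net,
        removed_edges=removed,
        planted_bicliques=planted_bicliques,
        negatives=negatives,
    )


def benchmark_suite(
    spec_grid: list[SyntheticSpec],
    thresholds: list[SizeThreshold] | None = None,
    max_missing: int = 1,
) -> pd.DataFrame:
    """Score planted-edge recovery across a grid of synthetic networks.

    For each generated network, predictions at each threshold are scored
    against the deliberately removed edges (positives, restricted to
    predictable pairs) and the generated negatives. Returns one row per
    (spec, threshold) with the confusion counts and rates.
    """
    if thresholds is None:
        thresholds = [SizeThreshold(2, 2)]
    rows = []
    for spec_id, spec in enumerate(spec_grid):
        truth = generate(spec)
        positives = restrict_to_predictable(truth.removed_edges, truth.network)
        negatives = restrict_to_predictable(truth.negatives, truth.network)
        for t in thresholds:
            preds = prediction_edges(predict(truth.network, t, max_missing=max_missing))
            m = score_predictions(preds, positives, negatives)
            rows.append({"spec_id": spec_id, "seed": spec.seed,
                         "c_min": t.c_min, "p_min": t.p_min, **m.as_dict()})
    return pd.DataFrame(rows)
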