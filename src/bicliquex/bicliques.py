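"""Maximal biclique enumeration and biclique extension.

A biclique in a bipartite compound-protein network is a pair of node sets
(C, P) such that every compound in C interacts with every protein in P.
A *maximal* biclique admits no strict superset on either side that keeps
this completeness. Maximal bicliques correspond one-to-one to formal
concepts of the adjacency relation: pairs whose sides are each other's
common neighborhoods. Enumeration here uses the Close-by-One scheme
(closure-based depth-first search with a canonicity test), which visits
each concept exactly once.

Biclique *extension* predicts missing interactions: a node adjacent to all
but one (optionally all but two) members of the opposite side of a
qualifying biclique is proposed to also hold the missing interaction(s).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .network import BipartiteCPINetwork, density_summary


@dataclass(frozen=True)
class Biclique:
    """A complete bipartite subgraph, stored as two frozen node sets."""

    compound_set: frozenset[str]
    protein_set: frozenset[str]

    @property
    def c(self) -> int:
        return len(self.compound_set)

    @property
    def p(self) -> int:
        return len(self.protein_set)

    @property
    def sqrt_size(self) -> float:
        """Scalar size sqrt(c*p), for cross-network size comparisons."""
        return math.sqrt(self.c * self.p)

    def is_complete_in(self, net: BipartiteCPINetwork) -> bool:
        return all(
            net.has_edge(c, p) for c in self.compound_set for p in self.protein_set
        )


@dataclass(frozen=True)
class SizeThreshold:
    """Minimum compounds (c_min) and proteins (p_min) a biclique must have."""

    c_min: int = 2
    p_min: int = 2

    def __post_init__(self):
        if self.c_min < 2 or self.p_min < 2:
            raise ValueError("size thresholds require at least 2 nodes per side")

    def passes(self, biclique: Biclique) -> bool:
        return biclique.c >= self.c_min and biclique.p >= self.p_min


@dataclass(frozen=True)
class Prediction:
    """A proposed missing compound-protein edge.

    ``support`` counts the (biclique, candidate) derivations that produced
    the edge; ``missing_multiplicity`` is 1 when some derivation required
    inserting a single edge for its candidate, 2 when only two-edge
    insertions produced it.
    """

    compound: str
    protein: str
    support: int = 1
    missing_multiplicity: int = 1
    iteration: int = 1


def enumerate_maximal_bicliques(
    net: BipartiteCPINetwork, threshold: SizeThreshold = SizeThreshold()
) -> list[Biclique]:
    """All maximal bicliques with c >= c_min and p >= p_min.

    Overlapping bicliques are returned as separate entries; an edge may
    belong to several. Results are deterministic (sorted node order).
    """
    comp_adj = net.compound_neighbors()
    all_bicliques = _enumerate_concepts(comp_adj, net.protein_neighbors())
    out = [b for b in all_bicliques if threshold.passes(b)]
    out.sort(key=lambda b: (-b.c * b.p, sorted(b.compound_set), sorted(b.protein_set)))
    return out


def _enumerate_concepts(
    comp_adj: dict[str, set[str]], prot_adj: dict[str, set[str]]
) -> list[Biclique]:
    """Close-by-One enumeration of all concepts with both sides non-empty."""
    proteins = sorted(prot_adj)
    pindex = {p: i for i, p in enumerate(proteins)}
    all_compounds = frozenset(comp_adj)
    results: list[Biclique] = []

    def common_proteins(extent: frozenset[str]) -> frozenset[str]:
        it = iter(extent)
        acc = set(comp_adj[next(it)])
        for c in it:
            acc &= comp_adj[c]
            if not acc:
                break
        return frozenset(acc)

    # Iterative DFS to avoid recursion limits on deep concept lattices.
    top_intent = common_proteins(all_compounds) if all_compounds else frozenset()
    stack: list[tuple[frozenset[str], frozenset[str], int]] = [
        (all_compounds, top_intent, 0)
    ]
    while stack:
        extent, intent, start = stack.pop()
        if extent and intent:
            results.append(Biclique(extent, intent))
        for j in range(start, len(proteins)):
            pj = proteins[j]
            if pj in intent:
                continue
            new_extent = extent & prot_adj[pj]
            if not new_extent:
                continue
            new_intent = common_proteins(new_extent)
            # canonicity: closure must not introduce an earlier protein
            if any(pindex[q] < j and q not in intent for q in new_intent):
                continue
            stack.append((new_extent, new_intent, j + 1))
    return results


def biclique_size_census(bicliques: list[Biclique]) -> pd.DataFrame:
    """Frequency table of biclique shapes: columns (c, p, count, sqrt_size)."""
    counts = Counter((b.c, b.p) for b in bicliques)
    rows = [
        (c, p, n, math.sqrt(c * p)) for (c, p), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["c", "p", "count", "sqrt_size"])


def extend_bicliques(
    net: BipartiteCPINetwork,
    threshold: SizeThreshold = SizeThreshold(),
    max_missing: int = 1,
    two_edge_min_side: int = 4,
    iteration: int = 1,
    bicliques: list[Biclique] | None = None,
) -> list[Prediction]:
    """Predict missing edges by one- and two-edge biclique extension.

    For each maximal biclique (C, P) passing ``threshold``: a compound
    outside C adjacent to exactly |P|-1 proteins of P yields a prediction
    for its single missing edge (symmetrically for proteins). With
    ``max_missing=2``, candidates missing exactly two edges to a side of
    size >= ``two_edge_min_side`` yield both missing edges. Predictions
    are deduplicated per edge with aggregated support; existing edges are
    never predicted.

    Maximality does not depend on the size threshold, so a precomputed
    ``bicliques`` list (e.g. from a looser threshold) may be supplied; it
    is re-filtered by ``threshold`` before extension.
    """
    if max_missing not in (1, 2):
        raise ValueError("max_missing must be 1 or 2")
    if bicliques is None:
        bicliques = enumerate_maximal_bicliques(net, threshold)
    else:
        bicliques = [b for b in bicliques if threshold.passes(b)]
    comp_adj = net.compound_neighbors()
    prot_adj = net.protein_neighbors()

    support: Counter[tuple[str, str]] = Counter()
    multiplicity: dict[tuple[str, str], int] = {}

    def record(edge: tuple[str, str], mult: int) -> None:
        support[edge] += 1
        prev = multiplicity.get(edge)
        multiplicity[edge] = mult if prev is None else min(prev, mult)

    for b in bicliques:
        # compound candidates joining the protein side
        for x, nbrs in comp_adj.items():
            if x in b.compound_set:
                continue
            missing = b.protein_set - nbrs
            if len(missing) == 1:
                record((x, next(iter(missing))), 1)
            elif (
                max_missing == 2
                and len(missing) == 2
                and b.p >= two_edge_min_side
            ):
                for q in missing:
                    record((x, q), 2)
        # protein candidates joining the compound side
        for y, nbrs in prot_adj.items():
            if y in b.protein_set:
                continue
            missing = b.compound_set - nbrs
            if len(missing) == 1:
                record((next(iter(missing)), y), 1)
            elif (
                max_missing == 2
                and len(missing) == 2
                and b.c >= two_edge_min_side
            ):
                for c in missing:
                    record((c, y), 2)

    return [
        Prediction(
            compound=c,
            protein=p,
            support=support[(c, p)],
            missing_multiplicity=multiplicity[(c, p)],
            iteration=iteration,
        )
        for (c, p) in support
    ]


def predict(
    net: BipartiteCPINetwork,
    threshold: SizeThreshold = SizeThreshold(),
    max_missing: int = 1,
    two_edge_min_side: int = 4,
    iteration: int = 1,
) -> list[Prediction]:
    """Enumerate qualifying maximal bicliques and extend them.

    Output is sorted by (support desc, compound id, protein id) so runs
    are deterministic.
    """
    preds = extend_bicliques(
        net, threshold, max_missing=max_missing,
        two_edge_min_side=two_edge_min_side, iteration=iteration,
    )
    preds.sort(key=lambda pr: (-pr.support, pr.compound, pr.protein))
    return preds


def prediction_edges(predictions: list[Prediction]) -> set[tuple[str, str]]:
    return {(pr.compound, pr.protein) for pr in predictions}


def iterate_to_convergence(
    net: BipartiteCPINetwork,
    threshold: SizeThreshold = SizeThreshold(),
    max_missing: int = 1,
    two_edge_min_side: int = 4,
    stop_new_below: int = 1,
    max_iter: int = 50,
) -> tuple[BipartiteCPINetwork, pd.DataFrame]:
    """Repeatedly predict and insert edges until (near-)convergence.

    Each iteration computes all predictions against the iteration-start
    network (batch semantics), inserts them, and records (iteration,
    n_new, density). Stops when fewer than ``stop_new_below`` new edges
    appear or after ``max_iter`` iterations. Densities are non-decreasing
    since edges are only added between existing nodes.
    """
    if stop_new_below < 1:
        raise ValueError("stop_new_below must be >= 1")
    history = []
    current = net
    for it in range(1, max_iter + 1):
        preds = predict(
            current, threshold, max_missing=max_missing,
            two_edge_min_side=two_edge_min_side, iteration=it,
        )
        new_edges = prediction_edges(preds)
        if new_edges:
            current = current.with_added_edges(sorted(new_edges))
        history.append(
            {
                "iteration": it,
                "n_new": len(new_edges),
                "density": density_summary(current).density,
            }
        )
        if len(new_edges) < stop_new_below:
            break
    return current, pd.DataFrame(history)


def write_predictions(predictions: list[Prediction], path) -> None:
    """Prediction TSV: compound, protein, support, missing_multiplicity, iteration."""
    df = pd.DataFrame(
        [
            (pr.compound, pr.protein, pr.support, pr.missing_multiplicity, pr.iteration)
            for pr in predictions
        ],
        columns=["compound_id", "protein_id", "support", "missing_multiplicity", "iteration"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_bicliques(bicliques: list[Biclique], path) -> None:
    """Biclique membership TSV: biclique_id, side, member_id."""
    rows = []
    for i, b in enumerate(bicliques):
        rows.extend((i, "compound", c) for c in sorted(b.compound_set))
        rows.extend((i, "protein", p) for p in sorted(b.protein_set))
    pd.DataFrame(rows, columns=["biclique_id", "side", "member_id"]).to_csv(
        path, sep="\t", index=False
    )
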