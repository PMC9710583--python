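"""Degree-preserving randomization of bipartite networks.

The edge-switch (switching-chain) algorithm repeatedly picks two edges
(c1, p1), (c2, p2) with distinct endpoints and rewires them to
(c1, p2), (c2, p1) when neither target edge already exists. Every node's
degree, the edge count and bipartiteness are invariant; with enough
accepted swaps the result approximates a uniform draw from the set of
bipartite graphs with the given degree sequences.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .network import BipartiteCPINetwork


@dataclass(frozen=True)
class RewireReport:
    attempted_swaps: int
    accepted_swaps: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "attempted_swaps": self.attempted_swaps,
                "accepted_swaps": self.accepted_swaps,
                "seed": self.seed,
            }
        )


def default_n_swaps(n_edges: int, epsilon: float = 1e-3) -> int:
    """Switching-chain mixing heuristic: ceil(|E| * ln(1/epsilon)) attempts."""
    return math.ceil(n_edges * math.log(1.0 / epsilon))


def edge_switch_randomize(
    net: BipartiteCPINetwork, n_swaps: int | None = None, seed: int = 0
) -> tuple[BipartiteCPINetwork, RewireReport]:
    """Randomize a network while preserving both degree sequences exactly.

    Rejected proposals (shared endpoint or an already existing target
    edge) count toward ``attempted_swaps``, bounding the runtime. Edge
    score channels follow the compound endpoint's original edge.
    """
    if net.n_edges < 2:
        raise ValueError("edge-switch randomization needs at least 2 edges")
    if n_swaps is None:
        n_swaps = default_n_swaps(net.n_edges)
    rng = np.random.default_rng(seed)

    edge_list = sorted(net.edges)
    scores = [dict(net.edges[e]) for e in edge_list]
    edge_set = set(edge_list)
    m = len(edge_list)

    accepted = 0
    pairs = rng.integers(0, m, size=(n_swaps, 2))
    for i, j in pairs:
        if i == j:
            continue
        c1, p1 = edge_list[i]
        c2, p2 = edge_list[j]
        if c1 == c2 or p1 == p2:
            continue
        e1, e2 = (c1, p2), (c2, p1)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((c1, p1))
        edge_set.discard((c2, p2))
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[i], edge_list[j] = e1, e2
        accepted += 1

    randomized = BipartiteCPINetwork(
        net.compounds.values(),
        net.proteins.values(),
        {e: s for e, s in zip(edge_list, scores)},
        provenance=f"{net.provenance} [edge-switch seed={seed}]",
    )
    return randomized, RewireReport(attempted_swaps=n_swaps, accepted_swaps=accepted, seed=seed)
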