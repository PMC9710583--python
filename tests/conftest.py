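import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bicliquex import BipartiteCPINetwork, CompoundRecord, ProteinRecord


def make_network(edges, compounds=None, proteins=None, channel="experimental",
                 scores=None):
    """Small-network helper: edges is an iterable of (compound, protein)."""
    edges = list(edges)
    if compounds is None:
        compounds = sorted({c for c, _ in edges})
    if proteins is None:
        proteins = sorted({p for _, p in edges})
    if scores is None:
        scores = {e: 1.0 for e in edges}
    return BipartiteCPINetwork(
        [CompoundRecord(id=c) for c in compounds],
        [ProteinRecord(id=p) for p in proteins],
        {e: {channel: scores[e]} for e in edges},
    )


def random_bipartite(n_compounds, n_proteins, edge_prob, seed):
    """Seeded Erdos-Renyi bipartite network (compounds x0.., proteins y0..)."""
    rng = np.random.default_rng(seed)
    edges = [
        (f"x{i}", f"y{j}")
        for i in range(n_compounds)
        for j in range(n_proteins)
        if rng.random() < edge_prob
    ]
    compounds = [f"x{i}" for i in range(n_compounds)]
    proteins = [f"y{j}" for j in range(n_proteins)]
    return make_network(edges, compounds=compounds, proteins=proteins)


@pytest.fixture
def fig1_toy():
    """Biclique {c1,c2,c3} x {p1,p2} plus an external compound c4-p1."""
    return make_network(
        [(c, p) for c in ("c1", "c2", "c3") for p in ("p1", "p2")] + [("c4", "p1")]
    )


@pytest.fixture
def two_stage_net():
    """Hand-built network needing exactly two prediction-bearing iterations.

    Round 1 completes {c1,c2}x{p1,p2} and {c3,c5}x{p1,p3} extensions;
    only the grown network lets c4 (adjacent to p1, p3) reach p2.
    """
    return make_network(
        [("c1", "p1"), ("c1", "p2"), ("c2", "p1"), ("c2", "p2"),
         ("c3", "p1"), ("c3", "p3"), ("c5", "p1"), ("c5", "p3"),
         ("c4", "p3")]
    )
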