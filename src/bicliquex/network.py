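"""Bipartite compound-protein interaction (CPI) network data model.

The central object is :class:`BipartiteCPINetwork`: two disjoint node
partitions (small-molecule compounds and proteins) joined by scored
undirected edges. Edge scores live in named channels (e.g. ``experimental``,
``combined``) on a 0-1 confidence scale, following the convention of
public chemical-protein association databases.

This module also provides the cleanup filters applied before biclique
analysis: a minimum heavy-atom size filter for compounds, removal of
drug-like / non-metabolic compound categories, and pruning of degree-1
nodes (which can never belong to a biclique with at least two nodes per
side).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DROP_CATEGORIES = frozenset({"antibiotic", "hormone_transmitter", "steroid"})


@dataclass(frozen=True)
class CompoundRecord:
    """A small-molecule node.

    ``heavy_atoms`` is the number of non-hydrogen atoms parsed from the
    SMILES string, or ``None`` when the SMILES is absent or unparseable.
    ``kegg_c_numbers`` / ``kegg_d_numbers`` hold KEGG compound ('C') and
    drug ('D') identifiers; ``category_flags`` hold annotation labels such
    as ``antibiotic``.
    """

    id: str
    smiles: str | None = None
    kegg_c_numbers: frozenset[str] = frozenset()
    kegg_d_numbers: frozenset[str] = frozenset()
    category_flags: frozenset[str] = frozenset()
    heavy_atoms: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "kegg_c_numbers", frozenset(self.kegg_c_numbers))
        object.__setattr__(self, "kegg_d_numbers", frozenset(self.kegg_d_numbers))
        object.__setattr__(self, "category_flags", frozenset(self.category_flags))
        if self.heavy_atoms is not None and self.heavy_atoms < 0:
            raise ValueError(f"heavy_atoms must be non-negative, got {self.heavy_atoms}")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein node, optionally carrying a sequence and pathway annotations."""

    id: str
    sequence: str | None = None
    pathway_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "pathway_ids", frozenset(self.pathway_ids))


@dataclass(frozen=True)
class DensitySummary:
    """Edge density of a bipartite network: D = N_i / (c * p)."""

    n_interactions: int
    n_compounds: int
    n_proteins: int
    density: float


class BipartiteCPINetwork:
    """Bipartite network of compounds and proteins with scored edges.

    Invariants enforced on construction:

    * strict bipartiteness — each edge joins a known compound id to a
      known protein id;
    * compound and protein id spaces are disjoint;
    * no duplicate edges (identified by the (compound, protein) pair);
    * every confidence score lies in [0, 1].
    """

    def __init__(
        self,
        compounds: Iterable[CompoundRecord],
        proteins: Iterable[ProteinRecord],
        edges: Mapping[tuple[str, str], Mapping[str, float]],
        provenance: str = "",
    ):
        self.compounds: dict[str, CompoundRecord] = {}
        for c in compounds:
            if c.id in self.compounds:
                raise ValueError(f"duplicate compound id {c.id!r}")
            self.compounds[c.id] = c
        self.proteins: dict[str, ProteinRecord] = {}
        for p in proteins:
            if p.id in self.proteins:
                raise ValueError(f"duplicate protein id {p.id!r}")
            if p.id in self.compounds:
                raise ValueError(f"id {p.id!r} used for both a compound and a protein")
            self.proteins[p.id] = p
        self.edges: dict[tuple[str, str], dict[str, float]] = {}
        for (cid, pid), channels in edges.items():
            if cid not in self.compounds:
                raise ValueError(f"edge ({cid!r}, {pid!r}) references unknown compound {cid!r}")
            if pid not in self.proteins:
                raise ValueError(f"edge ({cid!r}, {pid!r}) references unknown protein {pid!r}")
            ch = {str(k): float(v) for k, v in channels.items()}
            for name, score in ch.items():
                if not (0.0 <= score <= 1.0):
                    raise ValueError(
                        f"score {score} on channel {name!r} of edge ({cid!r}, {pid!r}) "
                        "outside [0, 1]"
                    )
            self.edges[(cid, pid)] = ch
        self.provenance = provenance

    # -- basic accessors -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def compound_ids(self) -> set[str]:
        return set(self.compounds)

    def protein_ids(self) -> set[str]:
        return set(self.proteins)

    def has_edge(self, compound_id: str, protein_id: str) -> bool:
        return (compound_id, protein_id) in self.edges

    def compound_neighbors(self) -> dict[str, set[str]]:
        """Adjacency from compound id to the set of protein ids it touches."""
        adj: dict[str, set[str]] = {c: set() for c in self.compounds}
        for cid, pid in self.edges:
            adj[cid].add(pid)
        return adj

    def protein_neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {p: set() for p in self.proteins}
        for cid, pid in self.edges:
            adj[pid].add(cid)
        return adj

    def degree(self, node_id: str) -> int:
        if node_id in self.compounds:
            return sum(1 for (c, _p) in self.edges if c == node_id)
        if node_id in self.proteins:
            return sum(1 for (_c, p) in self.edges if p == node_id)
        raise KeyError(node_id)

    # -- derived networks ------------------------------------------------

    def subnetwork(self, keep_edges: Iterable[tuple[str, str]]) -> "BipartiteCPINetwork":
        """New network restricted to ``keep_edges``; isolated nodes dropped."""
        keep = {e: dict(self.edges[e]) for e in keep_edges}
        cids = {c for c, _ in keep}
        pids = {p for _, p in keep}
        return BipartiteCPINetwork(
            [self.compounds[c] for c in sorted(cids)],
            [self.proteins[p] for p in sorted(pids)],
            keep,
            provenance=self.provenance,
        )

    def with_added_edges(
        self, new_edges: Iterable[tuple[str, str]], channel: str = "predicted", score: float = 1.0
    ) -> "BipartiteCPINetwork":
        """New network with extra edges between existing nodes."""
        edges = {e: dict(ch) for e, ch in self.edges.items()}
        for cid, pid in new_edges:
            if cid not in self.compounds or pid not in self.proteins:
                raise ValueError(f"edge ({cid!r}, {pid!r}) references an unknown node")
            if (cid, pid) not in edges:
                edges[(cid, pid)] = {channel: score}
        return BipartiteCPINetwork(
            self.compounds.values(), self.proteins.values(), edges, provenance=self.provenance
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<BipartiteCPINetwork {len(self.compounds)} compounds x "
            f"{len(self.proteins)} proteins, {self.n_edges} edges>"
        )


def build_network(
    compound_records: Iterable[CompoundRecord],
    protein_records: Iterable[ProteinRecord],
    edge_table: pd.DataFrame | Iterable[tuple],
    provenance: str = "",
) -> BipartiteCPINetwork:
    """Assemble a network from node records and an edge table.

    ``edge_table`` rows are ``(compound_id, protein_id, {channel: score})``
    tuples or a DataFrame with columns ``compound``, ``protein`` plus one
    column per score channel. Duplicate (compound, protein) rows collapse
    to a single edge keeping the maximum score per channel.
    """
    compound_records = list(compound_records)
    protein_records = list(protein_records)
    known_c = {c.id for c in compound_records}
    known_p = {p.id for p in protein_records}

    if isinstance(edge_table, pd.DataFrame):
        channel_cols = [c for c in edge_table.columns if c not in ("compound", "protein")]
        rows = (
            (r.compound, r.protein, {ch: getattr(r, ch) for ch in channel_cols})
            for r in edge_table.itertuples(index=False)
        )
    else:
        rows = iter(edge_table)

    edges: dict[tuple[str, str], dict[str, float]] = {}
    for i, (cid, pid, channels) in enumerate(rows):
        if cid not in known_c:
            raise ValueError(f"edge row {i}: unknown compound id {cid!r}")
        if pid not in known_p:
            raise ValueError(f"edge row {i}: unknown protein id {pid!r}")
        key = (cid, pid)
        if key in edges:
            for ch, score in channels.items():
                prev = edges[key].get(ch)
                edges[key][ch] = float(score) if prev is None else max(prev, float(score))
        else:
            edges[key] = {ch: float(v) for ch, v in channels.items()}
    return BipartiteCPINetwork(compound_records, protein_records, edges, provenance=provenance)


def filter_by_confidence(
    net: BipartiteCPINetwork, channel: str, threshold: float
) -> BipartiteCPINetwork:
    """Retain edges whose ``channel`` score is >= ``threshold`` (inclusive).

    Nodes left without edges are dropped. The inclusive boundary means a
    0.4 threshold keeps a 0.40-scored edge ("medium" confidence).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    for e, ch in net.edges.items():
        if channel not in ch:
            raise ValueError(f"edge {e} lacks score channel {channel!r}")
    keep = [e for e, ch in net.edges.items() if ch[channel] >= threshold]
    return net.subnetwork(keep)


def heavy_atom_count(smiles: str) -> int | None:
    """Number of non-hydrogen atoms in a SMILES string.

    Returns ``None`` for an unparseable SMILES (logged); the size filter
    then leaves the compound alone, since removal requires positive
    evidence of small size.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        logger.warning("unparseable SMILES %r; heavy-atom count unknown", smiles)
        return None
    return mol.GetNumHeavyAtoms()


def annotate_heavy_atoms(net: BipartiteCPINetwork) -> BipartiteCPINetwork:
    """Fill in ``heavy_atoms`` from SMILES for compounds missing it."""
    new_compounds = []
    for c in net.compounds.values():
        if c.heavy_atoms is None and c.smiles:
            c = replace(c, heavy_atoms=heavy_atom_count(c.smiles))
        new_compounds.append(c)
    return BipartiteCPINetwork(
        new_compounds, net.proteins.values(), net.edges, provenance=net.provenance
    )


def cleanup_network(
    net: BipartiteCPINetwork,
    min_heavy_atoms: int = 5,
    drop_categories: frozenset[str] = DEFAULT_DROP_CATEGORIES,
    require_c_number: bool = True,
) -> BipartiteCPINetwork:
    """Remove non-metabolic and uninformative compounds with their edges.

    Removes compounds that (a) have a known heavy-atom count below
    ``min_heavy_atoms`` (ions and other very small species), (b) carry any
    category flag in ``drop_categories``, or (c) — when ``require_c_number``
    — have a KEGG 'D' (drug) number without a 'C' (compound) number, or no
    KEGG mapping at all. The filters are pure per-node predicates, so
    their application order is irrelevant and the operation is idempotent.
    """
    drop_categories = frozenset(drop_categories)
    dropped: list[str] = []
    for c in net.compounds.values():
        if c.heavy_atoms is not None and c.heavy_atoms < min_heavy_atoms:
            dropped.append(c.id)
        elif c.category_flags & drop_categories:
            dropped.append(c.id)
        elif require_c_number and not c.kegg_c_numbers:
            # D-number-only drugs and compounds with no KEGG mapping go;
            # a D number alongside a C number is retained.
            dropped.append(c.id)
    dropped_set = set(dropped)
    if dropped_set:
        logger.info("cleanup: removing %d compounds", len(dropped_set))
    keep = [e for e in net.edges if e[0] not in dropped_set]
    return net.subnetwork(keep)


def prune_degree_one(net: BipartiteCPINetwork, mode: str = "single_pass") -> BipartiteCPINetwork:
    """Remove nodes with exactly one interaction (cannot join any biclique).

    ``single_pass`` removes, simultaneously, every node whose degree in the
    input is 1; ``fixpoint`` repeats until no degree-1 node remains; ``off``
    returns the input unchanged.
    """
    if mode not in ("single_pass", "fixpoint", "off"):
        raise ValueError(f"mode must be single_pass, fixpoint or off, got {mode!r}")
    if mode == "off":
        return net
    current = net
    while True:
        deg = Counter()
        for cid, pid in current.edges:
            deg[cid] += 1
            deg[pid] += 1
        doomed = {n for n, d in deg.items() if d == 1}
        if not doomed:
            return current
        keep = [e for e in current.edges if e[0] not in doomed and e[1] not in doomed]
        current = current.subnetwork(keep)
        if mode == "single_pass":
            return current


def density_summary(net: BipartiteCPINetwork) -> DensitySummary:
    """Network density D = N_i / (c * p); 0 when either partition is empty."""
    c, p = len(net.compounds), len(net.proteins)
    density = net.n_edges / (c * p) if c and p else 0.0
    return DensitySummary(net.n_edges, c, p, density)


def degree_distribution(net: BipartiteCPINetwork, side: str) -> pd.DataFrame:
    """Table of (degree, frequency) for one partition.

    Frequencies sum to the number of nodes on that side.
    """
    if side not in ("compound", "protein"):
        raise ValueError(f"side must be 'compound' or 'protein', got {side!r}")
    adj = net.compound_neighbors() if side == "compound" else net.protein_neighbors()
    counts = Counter(len(v) for v in adj.values())
    rows = sorted(counts.items())
    return pd.DataFrame(rows, columns=["degree", "frequency"])
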