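"""Pathway over-representation analysis of protein sets.

Standard hypergeometric (one-tailed Fisher) enrichment: for a query set
of proteins (e.g. those involved in predicted interactions), each pathway
is tested for over-representation against a background universe, with
Benjamini-Hochberg control of the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    k: int            # query members annotated to the pathway
    n: int            # annotated query size
    K: int            # universe members annotated to the pathway
    N_univ: int       # universe size
    fold_enrichment: float
    p_value: float
    p_adjust: float


def hypergeometric_enrichment(
    query_proteins: Iterable[str],
    annotation_map: Mapping[str, set[str]],
    universe: Iterable[str] | None = None,
    alpha: float = 0.01,
) -> list[EnrichmentRow]:
    """Hypergeometric pathway enrichment with BH correction.

    For each pathway with K annotated universe members, the upper-tail
    probability of drawing >= k annotated members in a query of size n
    from a universe of size N is computed; p-values are BH-adjusted
    across all tested pathways and rows with ``p_adjust < alpha`` are
    returned ordered by fold enrichment (descending). The universe
    defaults to every protein in ``annotation_map``.
    """
    if universe is None:
        universe_set = set(annotation_map)
    else:
        universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query = set(query_proteins) & universe_set
    n = len(query)
    N = len(universe_set)

    pathway_members: dict[str, set[str]] = {}
    for prot in universe_set:
        for pw in annotation_map.get(prot, ()):
            pathway_members.setdefault(pw, set()).add(prot)

    rows = []
    for pw, members in sorted(pathway_members.items()):
        K = len(members)
        k = len(members & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        fold = (k / n) / (K / N) if n else 0.0
        rows.append((pw, k, n, K, N, fold, p))
    if not rows:
        return []
    pvals = [r[6] for r in rows]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = [
        EnrichmentRow(pw, k, n_, K, N_, fold, p, float(padj))
        for (pw, k, n_, K, N_, fold, p), padj in zip(rows, p_adj)
        if padj < alpha
    ]
    out.sort(key=lambda r: (-r.fold_enrichment, r.pathway_id))
    return out


def read_annotation_map(path) -> dict[str, set[str]]:
    """Two-column TSV (protein_id, pathway_id); repeated rows allowed."""
    df = pd.read_csv(path, sep="\t", header=None, names=["protein", "pathway"], dtype=str)
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.protein, set()).add(r.pathway)
    return out


def write_enrichment(rows: list[EnrichmentRow], path) -> None:
    pd.DataFrame(
        [
            (r.pathway_id, r.k, r.n, r.K, r.N_univ, r.fold_enrichment, r.p_value, r.p_adjust)
            for r in rows
        ],
        columns=["pathway_id", "k", "n", "K", "N_univ", "fold_enrichment", "p_value", "p_adjust"],
    ).to_csv(path, sep="\t", index=False)
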