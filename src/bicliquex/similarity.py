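"""Molecular similarity of biclique members.

Compounds sharing a biclique bind the same proteins, so they are expected
to be chemically more alike than arbitrary compound pairs; likewise
proteins sharing a biclique should show higher sequence similarity. This
module quantifies that: Tanimoto similarity over circular substructure
fingerprints for compounds, local pairwise alignment scores (BLOSUM62,
affine gaps) for proteins, a Cohen's d effect size and a two-sided
rank-sum test between within- and between-biclique pair samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bicliques import Biclique
from .network import BipartiteCPINetwork

logger = logging.getLogger(__name__)


def morgan_features(smiles: str, radius: int = 2) -> frozenset[int] | None:
    """Hashed circular substructure feature set of a molecule.

    Returns ``None`` for an unparseable SMILES. The feature identifiers
    are the sparse (count-vector) keys of a Morgan fingerprint.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        logger.warning("unparseable SMILES %r; no fingerprint", smiles)
        return None
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    return frozenset(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())


def tanimoto_similarity(fingerprint_a, fingerprint_b) -> float:
    """|A ∩ B| / |A ∪ B| over structural feature sets; 0 when both empty."""
    a, b = set(fingerprint_a), set(fingerprint_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


_ALIGNER = None


def _get_aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _ALIGNER = aligner
    return _ALIGNER


def protein_similarity(seq_a: str, seq_b: str) -> float:
    """Best local-alignment score (BLOSUM62, gap open 11 / extend 1).

    Symmetric in its arguments; raw alignment score, not an E-value.
    """
    if not seq_a or not seq_b:
        raise ValueError("protein similarity requires non-empty sequences")
    return float(_get_aligner().score(seq_a.upper(), seq_b.upper()))


def cohens_d(x_values, y_values) -> float:
    """Standardized mean difference with pooled standard deviation.

    Returns NaN when the pooled standard deviation is zero (undefined).
    """
    x = np.asarray(list(x_values), dtype=float)
    y = np.asarray(list(y_values), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0.0:
        return float("nan")
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


@dataclass
class SimilarityStats:
    within_values: list[float]
    between_values: list[float]
    cohens_d: float
    ranksum_p: float
    n_pairs: int


def _ranksum_p(x: list[float], y: list[float]) -> float:
    """Two-sided rank-sum p; exact for small tie-free samples."""
    tie_free = len(set(x) | set(y)) == len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) < 50 and tie_free) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def within_between_similarity(
    net: BipartiteCPINetwork,
    bicliques: list[Biclique],
    side: str,
    n_pairs: int = 1000,
    seed: int = 0,
    fingerprint_radius: int = 2,
    similarity_fn=None,
) -> SimilarityStats:
    """Compare molecular similarity of within- vs between-biclique pairs.

    Samples ``n_pairs`` distinct node pairs sharing at least one biclique
    and ``n_pairs`` pairs sharing none (without replacement, no
    self-pairs), computes the side-appropriate similarity, Cohen's d
    (within minus between) and a two-sided rank-sum p-value. Pairs whose
    similarity cannot be computed (missing SMILES/sequence) are skipped
    and logged. ``similarity_fn(id_a, id_b) -> float`` overrides the
    default measure.
    """
    if side not in ("compound", "protein"):
        raise ValueError("side must be 'compound' or 'protein'")
    rng = np.random.default_rng(seed)

    if side == "compound":
        members = [sorted(b.compound_set) for b in bicliques]
        nodes = sorted(net.compounds)
    else:
        members = [sorted(b.protein_set) for b in bicliques]
        nodes = sorted(net.proteins)

    within_all: set[tuple[str, str]] = set()
    for mset in members:
        for i, a in enumerate(mset):
            for b in mset[i + 1:]:
                within_all.add((a, b))
    between_all = [
        (a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1:]
        if (a, b) not in within_all
    ]
    within_list = sorted(within_all)
    if not within_list or not between_all:
        raise ValueError(f"no admissible {side} pair in one of the strata")

    if similarity_fn is None:
        similarity_fn = _default_similarity(net, side, fingerprint_radius)

    def sample(pairs: list[tuple[str, str]]) -> list[float]:
        idx = rng.permutation(len(pairs))
        values = []
        skipped = 0
        for i in idx:
            if len(values) == n_pairs:
                break
            s = similarity_fn(*pairs[i])
            if s is None:
                skipped += 1
                continue
            values.append(s)
        if skipped:
            logger.info("skipped %d %s pairs lacking structure data", skipped, side)
        if len(values) < 2:
            raise ValueError(f"fewer than 2 scorable {side} pairs in a stratum")
        return values

    within = sample(within_list)
    between = sample(between_all)
    return SimilarityStats(
        within_values=within,
        between_values=between,
        cohens_d=cohens_d(within, between),
        ranksum_p=_ranksum_p(within, between),
        n_pairs=min(len(within), len(between)),
    )


def _default_similarity(net: BipartiteCPINetwork, side: str, radius: int):
    if side == "compound":
        cache: dict[str, frozenset[int] | None] = {}

        def fp(cid: str):
            if cid not in cache:
                smiles = net.compounds[cid].smiles
                cache[cid] = morgan_features(smiles, radius) if smiles else None
            return cache[cid]

        def sim(a: str, b: str):
            fa, fb = fp(a), fp(b)
            if fa is None or fb is None:
                return None
            return tanimoto_similarity(fa, fb)

        return sim

    def sim(a: str, b: str):
        sa, sb = net.proteins[a].sequence, net.proteins[b].sequence
        if not sa or not sb:
            return None
        return protein_similarity(sa, sb)

    return sim
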