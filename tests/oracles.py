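"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: exhaustive subset enumeration for
maximal bicliques, a scan over all non-edges for extension, a quadratic
Gotoh dynamic program for local alignment, and closed-form combinatorics
for the hypergeometric tail. None of it shares code with the package.
"""

from itertools import combinations
from math import comb


def brute_force_maximal_bicliques(comp_adj, prot_adj, c_min=2, p_min=2):
    """All maximal bicliques by testing every compound subset's common
    neighborhood and closing it back; returns a set of frozenset pairs."""
    compounds = sorted(comp_adj)
    found = set()
    for r in range(1, len(compounds) + 1):
        for subset in combinations(compounds, r):
            common_p = set(comp_adj[subset[0]])
            for c in subset[1:]:
                common_p &= comp_adj[c]
            if not common_p:
                continue
            # close back on the compound side
            extent = {c for c in compounds if common_p <= comp_adj[c]}
            found.add((frozenset(extent), frozenset(common_p)))
    return {
        (C, P) for C, P in found if len(C) >= c_min and len(P) >= p_min
    }


def brute_force_extension(comp_adj, prot_adj, bicliques, max_missing=1,
                          two_edge_min_side=4):
    """Predicted edges by scanning every non-edge against every biclique."""
    edges = {(c, p) for c, nbrs in comp_adj.items() for p in nbrs}
    predicted = set()
    for c in comp_adj:
        for p in prot_adj:
            if (c, p) in edges:
                continue
            for C, P in bicliques:
                if p in P and c not in C:
                    missing = P - comp_adj[c]
                    if len(missing) == 1 and p in missing:
                        predicted.add((c, p))
                        break
                    if (max_missing == 2 and len(missing) == 2 and p in missing
                            and len(P) >= two_edge_min_side):
                        predicted.add((c, p))
                        break
                if c in C and p not in P:
                    missing = C - prot_adj[p]
                    if len(missing) == 1 and c in missing:
                        predicted.add((c, p))
                        break
                    if (max_missing == 2 and len(missing) == 2 and c in missing
                            and len(C) >= two_edge_min_side):
                        predicted.add((c, p))
                        break
    return predicted


def gotoh_local_score(a, b, matrix, gap_open=11, gap_extend=1):
    """Smith-Waterman local alignment score with affine gaps (Gotoh DP)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]   # match/mismatch state
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i - 1][j - 1] + s,
                          Y[i - 1][j - 1] + s)
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct summation."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / total
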