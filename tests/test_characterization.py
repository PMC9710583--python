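import math

import numpy as np
import pytest

import bicliquex as bx
from bicliquex.enrichment import hypergeometric_enrichment
from bicliquex.similarity import _ranksum_p, morgan_features
from conftest import make_network
from oracles import gotoh_local_score, hypergeom_upper_tail


class TestTanimoto:
    def test_identical_smiles_score_one(self):
        fp = morgan_features("CC(=O)Oc1ccccc1C(=O)O")
        assert bx.tanimoto_similarity(fp, fp) == 1.0

    def test_feature_set_overlap(self):
        assert bx.tanimoto_similarity({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_disjoint_sets_score_zero_and_empty_convention(self):
        assert bx.tanimoto_similarity({1}, {2}) == 0.0
        assert bx.tanimoto_similarity(set(), set()) == 0.0

    def test_symmetric_and_bounded(self):
        a = morgan_features("CCO")
        b = morgan_features("CCCCO")
        s = bx.tanimoto_similarity(a, b)
        assert s == bx.tanimoto_similarity(b, a)
        assert 0.0 < s < 1.0

    def test_unparseable_smiles_has_no_fingerprint(self):
        assert morgan_features("((((") is None


class TestProteinSimilarity:
    SEQ_A = "MKTAYIAKQRQISFVKSHFSRQL"
    SEQ_B = "MKTAYIAKQRQISFVKSHFSRQH"

    def test_self_alignment_is_maximal(self):
        self_score = bx.protein_similarity(self.SEQ_A, self.SEQ_A)
        cross = bx.protein_similarity(self.SEQ_A, self.SEQ_B)
        assert self_score >= cross

    def test_symmetry(self):
        assert bx.protein_similarity(self.SEQ_A, self.SEQ_B) == \
            bx.protein_similarity(self.SEQ_B, self.SEQ_A)

    @pytest.mark.parametrize(
        "a,b",
        [
            ("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY"),
            ("MKVLAAGHHW", "MKVLGGHHWW"),
            ("WWWWYYYYFFFF", "AAAAGGGGSSSS"),
            ("MKTAYIAKQRQISFVKSHFS", "MKTAYIAKNRQISFVKSHFS"),
        ],
    )
    def test_matches_dynamic_programming_oracle(self, a, b):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        expected = gotoh_local_score(a, b, blosum, gap_open=11, gap_extend=1)
        assert bx.protein_similarity(a, b) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            bx.protein_similarity("", "MKT")


class TestCohensD:
    def test_identical_groups_give_zero(self):
        assert bx.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_value(self):
        d = bx.cohens_d([1, 1, 2, 2], [3, 3, 4, 4])
        assert d == pytest.approx(-2 / math.sqrt(1 / 3))

    def test_antisymmetric_under_group_swap(self):
        x, y = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0]
        assert bx.cohens_d(x, y) == pytest.approx(-bx.cohens_d(y, x))

    def test_zero_pooled_sd_flagged_as_nan(self):
        assert math.isnan(bx.cohens_d([2, 2], [5, 5]))


class TestWithinBetween:
    def _biclique_net(self):
        # two bicliques of compounds sharing a phenyl-acid scaffold;
        # background compounds are unrelated aliphatics
        scaffolds = {
            "c1": "c1ccccc1C(=O)O", "c2": "c1ccccc1CC(=O)O", "c3": "c1ccccc1CCC(=O)O",
            "c4": "c1ccc(O)cc1C(=O)O", "c5": "c1ccc(N)cc1C(=O)O",
        }
        background = {"b1": "CCCCCCCC", "b2": "CC(C)CC(C)O", "b3": "CCOCCOCC",
                      "b4": "CCCCN", "b5": "CC(C)(C)CO"}
        edges = [(c, p) for c in ("c1", "c2", "c3") for p in ("p1", "p2")]
        edges += [(c, p) for c in ("c4", "c5") for p in ("p3", "p4")]
        edges += [(b, "p5") for b in background]
        edges += [("b1", "p6"), ("b2", "p6")]
        smiles = {**scaffolds, **background}
        net = bx.BipartiteCPINetwork(
            [bx.CompoundRecord(id=c, smiles=s) for c, s in sorted(smiles.items())],
            [bx.ProteinRecord(id=f"p{i}") for i in range(1, 7)],
            {e: {"s": 1.0} for e in edges},
        )
        return net

    def test_constructed_separation_detected(self):
        net = self._biclique_net()
        cliques = bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2))
        stats = bx.within_between_similarity(net, cliques, "compound",
                                             n_pairs=30, seed=0)
        assert stats.cohens_d > 0
        assert stats.ranksum_p < 0.05

    def test_degenerate_identical_similarity(self):
        net = self._biclique_net()
        cliques = bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2))
        stats = bx.within_between_similarity(
            net, cliques, "compound", n_pairs=10, seed=0,
            similarity_fn=lambda a, b: 0.5)
        assert math.isnan(stats.cohens_d)
        assert stats.ranksum_p == pytest.approx(1.0)

    def test_same_seed_samples_same_pairs(self):
        net = self._biclique_net()
        cliques = bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2))
        s1 = bx.within_between_similarity(net, cliques, "compound", n_pairs=5, seed=7)
        s2 = bx.within_between_similarity(net, cliques, "compound", n_pairs=5, seed=7)
        assert s1.within_values == s2.within_values
        assert s1.between_values == s2.between_values

    def test_null_fixture_small_effect_size(self):
        # similarities drawn from one distribution regardless of stratum
        net = self._biclique_net()
        cliques = bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2))
        rng = np.random.default_rng(0)
        ds = []
        for seed in range(100):
            table = {}

            def sim(a, b):
                key = tuple(sorted((a, b)))
                if key not in table:
                    table[key] = float(rng.random())
                return table[key]

            stats = bx.within_between_similarity(net, cliques, "compound",
                                                 n_pairs=20, seed=seed,
                                                 similarity_fn=sim)
            ds.append(stats.cohens_d)
        assert abs(np.mean(ds)) < 0.2

    def test_empty_stratum_rejected(self):
        net = make_network([(f"c{i}", f"p{j}") for i in range(3) for j in range(2)])
        cliques = bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2))
        # every compound pair shares the single biclique: no between pairs
        with pytest.raises(ValueError, match="admissible"):
            bx.within_between_similarity(net, cliques, "compound", n_pairs=2, seed=0,
                                         similarity_fn=lambda a, b: 1.0)


class TestEnrichment:
    def _annotation(self, n_prot=20, pathway_size=5):
        ann = {f"q{i}": {"pwA"} for i in range(pathway_size)}
        ann.update({f"u{i}": set() for i in range(n_prot - pathway_size)})
        return ann

    def test_closed_form_case(self):
        ann = self._annotation()
        rows = hypergeometric_enrichment([f"q{i}" for i in range(5)], ann, alpha=0.01)
        assert len(rows) == 1
        row = rows[0]
        assert row.p_value == pytest.approx(1 / 15504, rel=1e-9)
        assert row.fold_enrichment == pytest.approx(4.0)
        assert row.k == row.n == row.K == 5 and row.N_univ == 20

    def test_query_equals_universe_is_unenriched(self):
        ann = {f"x{i}": {"pw1"} if i < 4 else {"pw2"} for i in range(12)}
        rows = hypergeometric_enrichment(list(ann), ann, alpha=1.1)
        for r in rows:
            assert r.fold_enrichment == pytest.approx(1.0)
            assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n,query_hits", [
        (10, 3, 4, 2), (15, 6, 5, 4), (20, 10, 8, 7), (12, 4, 6, 1),
    ])
    def test_matches_enumeration_oracle(self, N, K, n, query_hits):
        annotated = [f"a{i}" for i in range(K)]
        plain = [f"b{i}" for i in range(N - K)]
        ann = {p: {"pw"} for p in annotated}
        ann.update({p: set() for p in plain})
        query = annotated[:query_hits] + plain[: n - query_hits]
        rows = hypergeometric_enrichment(query, ann, alpha=1.1)
        row = next(r for r in rows if r.pathway_id == "pw")
        assert row.p_value == pytest.approx(
            hypergeom_upper_tail(query_hits, N, K, n), rel=1e-12)

    def test_bh_adjustment_is_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        ann = {}
        for i in range(40):
            ann[f"prot{i}"] = {f"pw{j}" for j in rng.choice(8, size=2, replace=False)}
        query = [f"prot{i}" for i in range(12)]
        rows = hypergeometric_enrichment(query, ann, alpha=1.1)
        by_p = sorted(rows, key=lambda r: r.p_value)
        adj = [r.p_adjust for r in by_p]
        assert all(b >= a for a, b in zip(adj, adj[1:]))
        assert all(r.p_adjust >= r.p_value for r in rows)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_enrichment(["x"], {}, universe=[])


class TestRankSum:
    def test_exact_used_for_small_tie_free_samples(self):
        # exact two-sided p for fully separated samples of size 3
        p = _ranksum_p([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1, rel=1e-9)  # 2 * 1/C(6,3)
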