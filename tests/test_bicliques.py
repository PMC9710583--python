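import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bicliquex as bx
from bicliquex.bicliques import prediction_edges
from conftest import make_network, random_bipartite
from oracles import brute_force_extension, brute_force_maximal_bicliques


def as_pairs(bicliques):
    return {(b.compound_set, b.protein_set) for b in bicliques}


class TestEnumeration:
    def test_complete_bipartite_is_a_single_biclique(self):
        net = make_network([(f"c{i}", f"p{j}") for i in range(3) for j in range(2)])
        found = bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2))
        assert as_pairs(found) == {
            (frozenset({"c0", "c1", "c2"}), frozenset({"p0", "p1"}))
        }

    def test_no_qualifying_biclique_when_one_edge_missing(self):
        net = make_network([("c1", "p1"), ("c1", "p2"), ("c2", "p1")])
        assert bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2)) == []

    @pytest.mark.parametrize("edge_prob", [0.3, 0.5, 0.7])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_subset_oracle(self, edge_prob, seed):
        net = random_bipartite(8, 8, edge_prob, seed=seed)
        found = bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2))
        expected = brute_force_maximal_bicliques(
            net.compound_neighbors(), net.protein_neighbors()
        )
        assert as_pairs(found) == expected

    def test_every_returned_biclique_is_complete_in_network(self):
        net = random_bipartite(10, 10, 0.4, seed=11)
        for b in bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2)):
            assert b.is_complete_in(net)

    def test_no_returned_biclique_contained_in_another(self):
        net = random_bipartite(8, 8, 0.5, seed=2)
        found = bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2))
        for a in found:
            for b in found:
                if a is not b:
                    assert not (
                        a.compound_set <= b.compound_set
                        and a.protein_set <= b.protein_set
                    )


class TestCensus:
    def test_counts_and_sqrt_size(self):
        b32 = bx.Biclique(frozenset("abc"), frozenset("xy"))
        b42 = bx.Biclique(frozenset("abcd"), frozenset("xz"))
        census = bx.biclique_size_census([b32, b42, b42])
        assert census.loc[census.c == 3, "count"].item() == 1
        assert census.loc[census.c == 4, "count"].item() == 2
        assert b42.sqrt_size == pytest.approx(math.sqrt(8))
        assert census["count"].sum() == 3


class TestExtension:
    def test_external_compound_predicts_single_missing_edge(self, fig1_toy):
        preds = bx.predict(fig1_toy, bx.SizeThreshold(2, 2))
        assert [(p.compound, p.protein) for p in preds] == [("c4", "p2")]
        assert preds[0].missing_multiplicity == 1

    def test_complete_network_yields_no_predictions(self):
        net = make_network([(f"c{i}", f"p{j}") for i in range(4) for j in range(3)])
        assert bx.predict(net, bx.SizeThreshold(2, 2)) == []

    @pytest.mark.parametrize("max_missing", [1, 2])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_non_edge_oracle(self, max_missing, seed):
        net = random_bipartite(10, 10, 0.5, seed=seed)
        comp_adj, prot_adj = net.compound_neighbors(), net.protein_neighbors()
        bicliques = brute_force_maximal_bicliques(comp_adj, prot_adj)
        expected = brute_force_extension(comp_adj, prot_adj, bicliques,
                                         max_missing=max_missing)
        got = prediction_edges(
            bx.predict(net, bx.SizeThreshold(2, 2), max_missing=max_missing)
        )
        assert got == expected

    def test_predictions_never_duplicate_existing_edges(self):
        net = random_bipartite(12, 12, 0.4, seed=9)
        for pr in bx.predict(net, bx.SizeThreshold(2, 2), max_missing=2):
            assert not net.has_edge(pr.compound, pr.protein)

    def test_overlapping_bicliques_aggregate_support(self):
        # two maximal bicliques sharing column p2 both imply (c5, p2)
        edges = [(c, p) for c in ("c1", "c2") for p in ("p1", "p2")]
        edges += [(c, p) for c in ("c3", "c4") for p in ("p2", "p3")]
        edges += [("c5", "p1"), ("c5", "p3")]
        net = make_network(edges)
        preds = {(p.compound, p.protein): p for p in bx.predict(net, bx.SizeThreshold(2, 2))}
        assert preds[("c5", "p2")].support == 2

    def test_two_edge_rule_gated_by_corresponding_side_size(self):
        # biclique with 4 proteins: compound missing two edges is eligible;
        # with the gate raised to 5 it is not. Threshold (2,3) keeps the
        # smaller overlapping biclique {c1,c2,c3}x{p1,p2} out of play so the
        # edges can only arise from the two-edge rule.
        edges = [(c, p) for c in ("c1", "c2") for p in ("p1", "p2", "p3", "p4")]
        edges += [("c3", "p1"), ("c3", "p2")]
        net = make_network(edges)
        with_gate4 = prediction_edges(
            bx.predict(net, bx.SizeThreshold(2, 3), max_missing=2, two_edge_min_side=4)
        )
        assert {("c3", "p3"), ("c3", "p4")} <= with_gate4
        with_gate5 = prediction_edges(
            bx.predict(net, bx.SizeThreshold(2, 3), max_missing=2, two_edge_min_side=5)
        )
        assert not ({("c3", "p3"), ("c3", "p4")} & with_gate5)

    def test_high_threshold_silences_all_predictions(self):
        net = random_bipartite(10, 10, 0.3, seed=4)
        assert bx.predict(net, bx.SizeThreshold(9, 9)) == []

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 500))
    def test_threshold_monotonicity(self, seed):
        net = random_bipartite(9, 9, 0.5, seed=seed)
        base = prediction_edges(bx.predict(net, bx.SizeThreshold(2, 2)))
        up_c = prediction_edges(bx.predict(net, bx.SizeThreshold(3, 2)))
        up_p = prediction_edges(bx.predict(net, bx.SizeThreshold(2, 3)))
        assert up_c <= base and up_p <= base

    def test_invariant_under_node_insertion_order(self):
        edges = [(f"c{i}", f"p{j}") for i in range(5) for j in range(4) if (i + j) % 3]
        net_fwd = make_network(edges, compounds=[f"c{i}" for i in range(5)],
                               proteins=[f"p{j}" for j in range(4)])
        net_rev = make_network(list(reversed(edges)),
                               compounds=[f"c{i}" for i in reversed(range(5))],
                               proteins=[f"p{j}" for j in reversed(range(4))])
        assert prediction_edges(bx.predict(net_fwd, bx.SizeThreshold(2, 2))) == \
            prediction_edges(bx.predict(net_rev, bx.SizeThreshold(2, 2)))


class TestPlantedRecovery:
    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), c=st.integers(3, 6), p=st.integers(3, 6))
    def test_single_removed_edge_recovered_exactly(self, seed, c, p):
        import numpy as np

        rng = np.random.default_rng(seed)
        full = [(f"c{i}", f"p{j}") for i in range(c) for j in range(p)]
        removed = full[rng.integers(len(full))]
        net = make_network([e for e in full if e != removed],
                           compounds=[f"c{i}" for i in range(c)],
                           proteins=[f"p{j}" for j in range(p)])
        got = prediction_edges(bx.predict(net, bx.SizeThreshold(c - 1, p - 1)))
        assert got == {removed}


class TestIteration:
    def test_saturated_network_converges_immediately(self):
        net = make_network([(f"c{i}", f"p{j}") for i in range(3) for j in range(3)])
        final, history = bx.iterate_to_convergence(net, bx.SizeThreshold(2, 2))
        assert len(history) == 1 and history.n_new.iloc[0] == 0
        assert final.n_edges == net.n_edges

    def test_two_stage_fixture_needs_exactly_two_productive_iterations(self, two_stage_net):
        final, history = bx.iterate_to_convergence(two_stage_net, bx.SizeThreshold(2, 2))
        productive = history[history.n_new > 0]
        assert len(productive) == 2
        assert final.n_edges == 15  # ends complete 5 x 3

    def test_density_history_monotone_and_bounded(self):
        net = random_bipartite(10, 8, 0.45, seed=21)
        _, history = bx.iterate_to_convergence(net, bx.SizeThreshold(2, 2), max_iter=20)
        dens = history.density.tolist()
        assert all(b >= a for a, b in zip(dens, dens[1:]))
        assert all(0 <= d <= 1 for d in dens)


class TestSerialization:
    def test_prediction_and_biclique_tsv(self, tmp_path, fig1_toy):
        preds = bx.predict(fig1_toy, bx.SizeThreshold(2, 2))
        cliques = bx.enumerate_maximal_bicliques(fig1_toy, bx.SizeThreshold(2, 2))
        import pandas as pd

        from bicliquex.bicliques import write_bicliques, write_predictions

        write_predictions(preds, tmp_path / "preds.tsv")
        write_bicliques(cliques, tmp_path / "bicliques.tsv")
        pdf = pd.read_csv(tmp_path / "preds.tsv", sep="\t")
        assert pdf.iloc[0].tolist() == ["c4", "p2", 1, 1, 1]
        bdf = pd.read_csv(tmp_path / "bicliques.tsv", sep="\t")
        assert len(bdf) == 5  # 3 compounds + 2 proteins
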