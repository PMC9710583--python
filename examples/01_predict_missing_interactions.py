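"""Predict a missing compound-protein interaction by biclique extension.

Builds a tiny network in which compounds c1-c3 all bind proteins p1 and
p2 (a 3x2 biclique), and a fourth compound c4 is known to bind p1 only.
Because c4 lacks exactly one edge to complete the biclique, the method
predicts the interaction (c4, p2).
"""

import bicliquex as bx

compounds = [bx.CompoundRecord(id=c) for c in ("c1", "c2", "c3", "c4")]
proteins = [bx.ProteinRecord(id=p) for p in ("p1", "p2")]
edges = [(c, p, {"experimental": 1.0}) for c in ("c1", "c2", "c3") for p in ("p1", "p2")]
edges.append(("c4", "p1", {"experimental": 1.0}))

net = bx.build_network(compounds, proteins, edges)
print(f"network: {len(net.compounds)} compounds, {len(net.proteins)} proteins, "
      f"{net.n_edges} edges, density {bx.density_summary(net).density:.3f}")

bicliques = bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2))
for b in bicliques:
    print(f"maximal biclique: {sorted(b.compound_set)} x {sorted(b.protein_set)} "
          f"(size sqrt(c*p) = {b.sqrt_size:.2f})")

predictions = bx.predict(net, bx.SizeThreshold(2, 2))
for pr in predictions:
    print(f"predicted interaction: {pr.compound} - {pr.protein} "
          f"(support {pr.support}, {pr.missing_multiplicity} edge inserted)")

# The single prediction (c4, p2) is the edge whose insertion makes c4 a
# full member of the existing biclique.
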