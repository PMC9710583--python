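"""Apply biclique extension iteratively until convergence.

The method only ever adds edges, so a natural worry is that iterating it
floods the network. This example inserts each round's predictions and
re-predicts until no new edge appears, tracking the density: it rises,
then plateaus well below a complete network.
"""

import bicliquex as bx

truth = bx.generate(bx.SyntheticSpec(background_edge_prob=0.02,
                                     holdout_per_biclique=1, seed=5))
print(f"start: {truth.network.n_edges} edges, "
      f"density {bx.density_summary(truth.network).density:.4f}")

final, history = bx.iterate_to_convergence(truth.network, bx.SizeThreshold(3, 2),
                                           max_iter=50)
print(history.to_string(index=False))
print(f"converged after {len(history)} iterations; final density "
      f"{bx.density_summary(final).density:.4f} (complete network would be 1.0)")
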