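# bicliquex

Biclique-extension link prediction for bipartite compound–protein
interaction (CPI) networks.

## The problem

Experimentally mapped interactions between small molecules and proteins
cover only a fraction of the true interactome. In a bipartite CPI network
a *biclique* is a pair of node sets (C compounds, P proteins) whose every
cross pair is a known interaction — a group of compounds binding exactly
the same proteins. Such agreement has a structural basis, so a node that
interacts with *almost* all of one side of a biclique very likely holds
the missing interaction too. `bicliquex` enumerates all maximal bicliques
of a network, extends them by candidates lacking exactly one (optionally
two) edges, and emits the missing edges as predictions:

- a compound x ∉ C adjacent to |P| − 1 proteins of P ⇒ predict the one
  missing edge (x, p\*), and symmetrically for proteins;
- predictions are emitted only for bicliques with at least `c_min`
  compounds and `p_min` proteins — the central precision/recall dial;
- a two-edge variant applies to candidates missing two edges to a side of
  size ≥ 4.

Around this core the package provides network cleanup (heavy-atom size
filter, drug/antibiotic removal, degree-1 pruning), hold-out validation
(TPR = TP/P, FPR = FP/N, F1, precision), a degree-preserving edge-switch
null model, iterative extension to convergence, molecular-similarity
characterization of biclique members (Tanimoto fingerprints, local
alignment scores, Cohen's d), hypergeometric pathway enrichment with
Benjamini–Hochberg correction, and a planted-biclique synthetic network
generator so the whole pipeline is testable without any database
download. Readers are included for chemical–protein link tables
(STITCH-style TSV), KGML pathway XML, and plain pair lists.

Intended users: computational biologists prioritizing candidate
compound–protein interactions for experimental validation, and method
developers needing a transparent, deterministic baseline for CPI link
prediction.

## Worked example

```python
import bicliquex as bx

compounds = [bx.CompoundRecord(id=c) for c in ("c1", "c2", "c3", "c4")]
proteins = [bx.ProteinRecord(id=p) for p in ("p1", "p2")]
edges = [(c, p, {"experimental": 1.0})
         for c in ("c1", "c2", "c3") for p in ("p1", "p2")]
edges.append(("c4", "p1", {"experimental": 1.0}))
net = bx.build_network(compounds, proteins, edges)

for b in bx.enumerate_maximal_bicliques(net, bx.SizeThreshold(2, 2)):
    print(sorted(b.compound_set), "x", sorted(b.protein_set))
for pr in bx.predict(net, bx.SizeThreshold(2, 2)):
    print("predicted:", pr.compound, "-", pr.protein)
```

prints

```
['c1', 'c2', 'c3'] x ['p1', 'p2']
predicted: c4 - p2
```

c1–c3 form a 3×2 biclique with p1 and p2; c4 binds p1 only, so inserting
the single edge (c4, p2) would make it a full member — that edge is the
prediction. The `examples/` directory holds runnable scripts for each
capability: prediction, hold-out validation sweeps, the randomized-network
control, iterative extension, and similarity/enrichment analysis. On the
bundled synthetic benchmark (50×80 nodes, six planted bicliques, 2%
background noise) the hold-out sweep reports, e.g., mean TPR 0.61 at
FPR 0.003 for threshold c=3, p=2, while the degree-preserving randomized
counterpart of the same network drops to TPR ≈ 0.04 — the structure, not
the degree sequence, carries the signal.

A thin CLI wraps the same functions:

```bash
bicliquex simulate --spec spec.json --out-dir sim/
bicliquex predict --input sim/network.tsv --thresholds 3:2 --out-dir out/
bicliquex validate --input sim/network.tsv --negatives sim/negatives.tsv \
    --thresholds 2:2,3:2 --seed 1 --out-dir val/
```

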