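"""Hold-out validation of biclique-extension predictions.

A fraction of the network's edges is removed (the positives), predictions
are computed on the reduced network, and recovery is scored against the
positives and an independent set of verified non-interactions (the
negatives). The reported rates are

    TPR = TP / P        FPR = FP / N
    F1  = 2 TP / (2 TP + FP + FN)
    PPV = TP / (TP + FP)

with P and N the sizes of the predictable positive and negative sets
(both endpoints present in the training network). The confirmation rate
TP / n_predicted estimates the expected experimental validation success
of the prediction list as a whole.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bicliques import (
    SizeThreshold,
    enumerate_maximal_bicliques,
    extend_bicliques,
    prediction_edges,
)
from .network import BipartiteCPINetwork

Pair = tuple[str, str]


@dataclass(frozen=True)
class Metrics:
    """Confusion counts and rates for one validation run."""

    tp: int
    fp: int
    fn: int
    n_positives: int
    n_negatives: int
    n_predicted: int

    def __post_init__(self):
        if self.tp > self.n_positives or self.fp > self.n_negatives:
            raise ValueError("confusion counts exceed class sizes")
        if self.fn != self.n_positives - self.tp:
            raise ValueError("fn must equal P - tp")

    @property
    def tpr(self) -> float:
        return self.tp / self.n_positives if self.n_positives else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / self.n_negatives if self.n_negatives else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def confirmation_rate(self) -> float:
        return self.tp / self.n_predicted if self.n_predicted else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "n_positives": self.n_positives, "n_negatives": self.n_negatives,
            "n_predicted": self.n_predicted,
            "tpr": self.tpr, "fpr": self.fpr, "f1": self.f1,
            "precision": self.precision, "confirmation_rate": self.confirmation_rate,
        }


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def holdout_split(
    net: BipartiteCPINetwork, fraction: float, seed: int
) -> tuple[BipartiteCPINetwork, set[Pair]]:
    """Remove round(fraction * |E|) uniformly sampled edges as positives.

    The training network keeps all remaining edges; no re-pruning is
    applied after removal, so some positives may be unrecoverable — they
    still count in P. Rounding is half-away-from-zero.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("holdout fraction must be in (0, 1)")
    n_remove = _round_half_away(fraction * net.n_edges)
    if n_remove >= net.n_edges:
        raise ValueError("holdout fraction would remove every edge")
    rng = np.random.default_rng(seed)
    edges = sorted(net.edges)
    removed_idx = rng.choice(len(edges), size=n_remove, replace=False)
    positives = {edges[i] for i in removed_idx}
    train = net.subnetwork([e for e in edges if e not in positives])
    return train, positives


def restrict_to_predictable(pairs: set[Pair], net: BipartiteCPINetwork) -> set[Pair]:
    """Keep pairs whose compound and protein both occur (with an edge) in net."""
    cids, pids = net.compound_ids(), net.protein_ids()
    return {(c, p) for c, p in pairs if c in cids and p in pids}


def score_predictions(
    predictions: set[Pair] | list, positives: set[Pair], negatives: set[Pair]
) -> Metrics:
    """Confusion counts of a prediction set against positive/negative pairs.

    Predictions matching neither set have unknown status and count only in
    ``n_predicted``.
    """
    if positives & negatives:
        raise ValueError("positive and negative sets overlap")
    if not isinstance(predictions, set):
        predictions = prediction_edges(predictions)
    tp = len(predictions & positives)
    fp = len(predictions & negatives)
    return Metrics(
        tp=tp,
        fp=fp,
        fn=len(positives) - tp,
        n_positives=len(positives),
        n_negatives=len(negatives),
        n_predicted=len(predictions),
    )


@dataclass
class SweepResult:
    """Per-threshold aggregate metrics over repeated hold-out runs."""

    table: pd.DataFrame
    best_threshold: SizeThreshold
    n_repeats: int
    seeds: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_repeats": self.n_repeats,
                "seeds": self.seeds,
                "best_threshold": [self.best_threshold.c_min, self.best_threshold.p_min],
                "rows": self.table.to_dict(orient="records"),
            }
        )


_METRIC_FIELDS = [
    "tp", "fp", "fn", "n_predicted", "tpr", "fpr", "f1", "precision", "confirmation_rate",
]


def run_validation(
    net: BipartiteCPINetwork,
    negatives: set[Pair],
    fraction: float,
    thresholds: list[SizeThreshold],
    n_repeats: int = 10,
    base_seed: int = 0,
    max_missing: int = 1,
    two_edge_min_side: int = 4,
) -> SweepResult:
    """Hold-out threshold sweep with repeated random splits.

    Each repeat r draws one split with seed ``base_seed + r`` and scores
    every threshold on that same split. Maximal bicliques are enumerated
    once per repeat at the loosest threshold and re-filtered per threshold
    (maximality is threshold-independent). Negatives that appear as edges
    of the input network are excluded from N before scoring (a pair cannot
    be both a reported interaction and a verified non-interaction); this
    also covers held-out positives.
    """
    if not thresholds:
        raise ValueError("at least one threshold required")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    loosest = SizeThreshold(
        c_min=min(t.c_min for t in thresholds), p_min=min(t.p_min for t in thresholds)
    )
    per_threshold: dict[SizeThreshold, list[Metrics]] = {t: [] for t in thresholds}
    clean_negatives = {e for e in negatives if e not in net.edges}
    if len(clean_negatives) < len(negatives):
        import logging

        logging.getLogger(__name__).info(
            "excluded %d negatives present as network edges",
            len(negatives) - len(clean_negatives),
        )
    seeds = [base_seed + r for r in range(n_repeats)]
    for seed in seeds:
        train, positives = holdout_split(net, fraction, seed)
        pos = restrict_to_predictable(positives, train)
        neg = restrict_to_predictable(clean_negatives, train)
        bicliques = enumerate_maximal_bicliques(train, loosest)
        for t in thresholds:
            preds = prediction_edges(
                extend_bicliques(
                    train, t, max_missing=max_missing,
                    two_edge_min_side=two_edge_min_side, bicliques=bicliques,
                )
            )
            per_threshold[t].append(score_predictions(preds, pos, neg))

    rows = []
    for t in thresholds:
        runs = per_threshold[t]
        row: dict = {"c_min": t.c_min, "p_min": t.p_min}
        for f in _METRIC_FIELDS:
            vals = np.array([getattr(m, f) for m in runs], dtype=float)
            row[f"{f}_mean"] = float(vals.mean())
            row[f"{f}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("n_predicted_mean").reset_index(drop=True)
    best_idx = int(table["f1_mean"].idxmax())
    best = SizeThreshold(int(table.loc[best_idx, "c_min"]), int(table.loc[best_idx, "p_min"]))
    return SweepResult(table=table, best_threshold=best, n_repeats=n_repeats, seeds=seeds)
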