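"""ROC / precision-recall evaluation of ranked edge lists against a gold
standard network (e.g. a literature-curated topology used as pseudo-gold
standard).

The candidate universe is every non-self pair over the gold network's
nodes (unordered pairs in undirected mode, ordered pairs in directed mode).
Predicted pairs absent from the ranking are appended at worst rank (score
−∞) so that every method is evaluated over the complete ranking.  Tied
scores are traversed as a single block, which makes the trapezoidal AUROC
identical to the Mann–Whitney U statistic with ties counted one half.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import RankedEdgeList, RegulatoryNetwork, canonical_pair


@dataclass
class EvaluationResult:
    labels: list[bool]
    scores: list[float]
    pairs: list[tuple[str, str]]
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    auroc: float
    aupr: float
    n_positives: int
    n_negatives: int

    def summary(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "n_positives": self.n_positives,
            "n_negatives": self.n_negatives,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.labels) + 1),
                "source": [p[0] for p in self.pairs],
                "target": [p[1] for p in self.pairs],
                "score": self.scores,
                "label": self.labels,
            }
        )


def label_predictions(
    pred: RankedEdgeList,
    gold: RegulatoryNetwork,
    mode: str = "undirected",
    include_self_loops: bool = False,
) -> tuple[list[bool], list[float], list[tuple[str, str]]]:
    """Ordered truth labels of a ranking against the gold network.

    Undirected mode: a predicted pair is true iff the gold network has an
    edge between the two nodes in either direction.  Directed mode: the
    ordered pair must match an edge's orientation.  Pairs of the candidate
    universe missing from the prediction are appended in lexicographic
    order with score −∞.  Self-loops are excluded by default.
    """
    if mode not in ("undirected", "directed"):
        raise ValueError(f"unknown mode {mode!r}")
    canon = gold.aliases.canonicalize
    gold_nodes = set(gold.node_names)
    gold_pairs = gold.undirected_pairs()
    gold_directed = {(e.source, e.target) for e in gold.edges if e.source != e.target}

    scored: dict[tuple[str, str], float] = {}
    for e in pred.entries:
        a, b = canon(e.pair[0]), canon(e.pair[1])
        if a not in gold_nodes or b not in gold_nodes:
            bad = a if a not in gold_nodes else b
            raise ValueError(f"predicted node {bad!r} is absent from the gold network")
        if a == b and not include_self_loops:
            continue
        key = canonical_pair(a, b) if mode == "undirected" else (a, b)
        if key not in scored or e.score > scored[key]:
            scored[key] = e.score

    nodes = sorted(gold_nodes)
    if mode == "undirected":
        universe = [canonical_pair(a, b) for a, b in itertools.combinations(nodes, 2)]
    else:
        universe = [(a, b) for a, b in itertools.permutations(nodes, 2)]

    ranked = sorted(
        (p for p in universe if p in scored), key=lambda p: (-scored[p], p)
    )
    missing = sorted(p for p in universe if p not in scored)
    pairs = ranked + missing
    scores = [scored[p] for p in ranked] + [-math.inf] * len(missing)
    if mode == "undirected":
        labels = [p in gold_pairs for p in pairs]
    else:
        labels = [p in gold_directed for p in pairs]
    if not any(labels):
        raise ValueError("gold network yields no positive pairs; evaluation undefined")
    return labels, scores, pairs


def _tie_blocks(labels: Sequence[bool], scores: Sequence[float] | None):
    """Cumulative (TP, FP) after each distinct-score block."""
    n = len(labels)
    if scores is None:
        scores = list(range(n, 0, -1))
    tp = fp = 0
    points = []
    i = 0
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        tp += sum(1 for k in range(i, j) if labels[k])
        fp += (j - i) - sum(1 for k in range(i, j) if labels[k])
        points.append((tp, fp))
        i = j
    return points


def roc_auroc(
    labels: Sequence[bool], scores: Sequence[float] | None = None
) -> tuple[list[tuple[float, float]], float]:
    """Step ROC curve and trapezoidal AUROC; tied blocks give one segment."""
    n_pos = sum(bool(l) for l in labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative label")
    points = [(0.0, 0.0)]
    for tp, fp in _tie_blocks(labels, scores):
        points.append((fp / n_neg, tp / n_pos))
    auroc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auroc += (x1 - x0) * (y0 + y1) / 2.0
    return points, float(auroc)


def pr_aupr(
    labels: Sequence[bool], scores: Sequence[float] | None = None
) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall step curve and non-interpolated AUPR.

    AUPR = Σ precision·Δrecall over cumulative cutoffs; a ranking that
    places every gold edge ahead of every non-edge scores exactly 1.
    """
    n_pos = sum(bool(l) for l in labels)
    if n_pos == 0:
        raise ValueError("PR requires at least one positive label")
    points = []
    aupr = 0.0
    prev_recall = 0.0
    for tp, fp in _tie_blocks(labels, scores):
        recall = tp / n_pos
        precision = tp / (tp + fp)
        points.append((recall, precision))
        aupr += precision * (recall - prev_recall)
        prev_recall = recall
    return points, float(aupr)


def precision_at_k(labels: Sequence[bool], k: int) -> float:
    """Precision of the top-k guesses."""
    if k < 1 or k > len(labels):
        raise ValueError("k must be within the number of predictions")
    return sum(bool(l) for l in labels[:k]) / k


def evaluate_ranking(
    pred: RankedEdgeList, gold: RegulatoryNetwork, mode: str = "undirected"
) -> EvaluationResult:
    """Full evaluation: labels, ROC/PR curves, AUROC and AUPR."""
    labels, scores, pairs = label_predictions(pred, gold, mode)
    roc_points, auroc = roc_auroc(labels, scores)
    pr_points, aupr = pr_aupr(labels, scores)
    n_pos = sum(bool(l) for l in labels)
    return EvaluationResult(
        labels=list(labels),
        scores=list(scores),
        pairs=list(pairs),
        roc_points=roc_points,
        pr_points=pr_points,
        auroc=auroc,
        aupr=aupr,
        n_positives=n_pos,
        n_negatives=len(labels) - n_pos,
    )


def plot_curves(result: EvaluationResult, path: str | Path) -> None:
    """ROC and PR curves side by side (PNG/SVG by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_roc, ax_pr) = plt.subplots(1, 2, figsize=(9, 4))
    xs, ys = zip(*result.roc_points)
    ax_roc.plot(xs, ys, drawstyle="steps-post")
    ax_roc.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax_roc.set_xlabel("FPR")
    ax_roc.set_ylabel("TPR")
    ax_roc.set_title(f"ROC (AUROC = {result.auroc:.3f})")
    xs, ys = zip(*result.pr_points)
    ax_pr.plot(xs, ys, drawstyle="steps-post")
    ax_pr.set_xlabel("recall")
    ax_pr.set_ylabel("precision")
    ax_pr.set_ylim(0, 1.05)
    ax_pr.set_title(f"PR (AUPR = {result.aupr:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
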