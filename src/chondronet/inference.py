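"""Individual network-inference methods and their average-rank consensus.

Each method maps a genes × samples expression matrix to a square confidence
matrix (higher = more likely a regulatory interaction) and a ranked edge
list.  The roster mirrors the standard GRN-inference families:

* statistical — absolute Pearson/Spearman correlation, a stability-selection
  sparse regression (TIGRESS-style), a regression-tree-ensemble importance
  method (GENIE3-style);
* information-theoretic — plug-in mutual information on equal-frequency
  bins, CLR background z-scoring, ARACNE data-processing-inequality
  pruning, MRMR relevance/redundancy scoring (MRNET-style);
* probabilistic — shrinkage Gaussian graphical model (partial correlations)
  and exhaustive Bayesian-Dirichlet parent-set scoring.

No single method wins across data sets, but a consensus of many does:
:func:`consensus_rank` collapses every method's output to undirected pairs,
converts scores to ranks and sorts pairs by mean rank (DREAM-style voting).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import rankdata, spearmanr

from .network import (
    RankedEdgeList,
    canonical_pair,
    collapse_undirected,
    ranked_list_from_scores,
)

METADATA_KEYS = ("study", "zone", "treatment", "replicate")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes × samples normalized log-scale expression with sample metadata.

    ``values``: DataFrame indexed by gene name with sample-id columns.
    ``metadata``: DataFrame indexed by sample id with study / zone /
    treatment / replicate columns (empty strings allowed).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene names in expression matrix")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.values.columns)
        self.metadata = self.metadata.reindex(self.values.columns)
        for key in METADATA_KEYS:
            if key not in self.metadata.columns:
                self.metadata[key] = "" if key != "replicate" else 0

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.metadata)

    def write_tsv(self, values_path: str | Path, metadata_path: str | Path | None = None):
        self.values.to_csv(values_path, sep="\t", index_label="gene", float_format="%.6g")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(
        cls, values_path: str | Path, metadata_path: str | Path | None = None
    ) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        meta = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
            meta.index = meta.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values, meta)


@dataclass
class ConfidenceMatrix:
    """Square non-negative confidence scores; symmetric when undirected."""

    node_order: list[str]
    values: np.ndarray
    directed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_order)
        if self.values.shape != (n, n):
            raise ValueError("confidence matrix must be square over node_order")
        if not np.isfinite(self.values).all():
            raise ValueError("confidence matrix contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("confidences must be non-negative")
        np.fill_diagonal(self.values, 0.0)
        if not self.directed:
            if not np.allclose(self.values, self.values.T):
                raise ValueError("undirected confidence matrix must be symmetric")
            # enforce bitwise symmetry (corrcoef etc. can differ in the last ulp)
            self.values = (self.values + self.values.T) / 2.0

    def score(self, a: str, b: str) -> float:
        i = self.node_order.index(a)
        j = self.node_order.index(b)
        return float(self.values[i, j])

    def to_ranked_edge_list(self) -> RankedEdgeList:
        scored: dict[tuple[str, str], float] = {}
        n = len(self.node_order)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                a, b = self.node_order[i], self.node_order[j]
                if self.directed:
                    scored[(a, b)] = float(self.values[i, j])
                else:
                    scored.setdefault(canonical_pair(a, b), float(self.values[i, j]))
        direction = "source_to_target" if self.directed else "undirected"
        return ranked_list_from_scores(scored, direction)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_order, columns=self.node_order)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class MethodResult:
    method: str
    confidence: ConfidenceMatrix
    ranking: RankedEdgeList = field(default=None)  # type: ignore[assignment]
    seed: int | None = None

    def __post_init__(self):
        if self.ranking is None:
            self.ranking = self.confidence.to_ranked_edge_list()


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _require_samples(expr: ExpressionMatrix, minimum: int, method: str) -> None:
    if expr.n_samples < minimum:
        raise ValueError(f"{method} requires at least {minimum} samples, got {expr.n_samples}")


def _check_variance(expr: ExpressionMatrix) -> None:
    X = expr.matrix()
    var = X.var(axis=1)
    for gene, v in zip(expr.genes, var):
        if v == 0.0:
            raise ValueError(f"gene {gene!r} has zero variance across samples")


def default_n_bins(n_samples: int) -> int:
    return max(2, int(math.floor(math.sqrt(n_samples))))


def equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization via rank quantiles; collapses tied
    boundaries and errors out if everything lands in a single bin."""
    binned = pd.qcut(pd.Series(x).rank(method="average"), n_bins, labels=False, duplicates="drop")
    codes = np.asarray(binned, dtype=float)
    if np.isnan(codes).any() or len(np.unique(codes)) < 2:
        raise ValueError("degenerate binning: all samples fall into one bin")
    return codes.astype(int)


def mutual_information_bits(bx: np.ndarray, by: np.ndarray) -> float:
    """Plug-in MI (bits) from two integer-coded vectors."""
    joint = pd.crosstab(pd.Series(bx), pd.Series(by)).to_numpy(dtype=float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def _mi_matrix(expr: ExpressionMatrix, n_bins: int | None) -> np.ndarray:
    n_bins = default_n_bins(expr.n_samples) if n_bins is None else n_bins
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    _require_samples(expr, n_bins, "mutual information")
    X = expr.matrix()
    binned = [equal_frequency_bins(X[i], n_bins) for i in range(X.shape[0])]
    n = X.shape[0]
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi[i, j] = mi[j, i] = mutual_information_bits(binned[i], binned[j])
    return mi


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# Statistical methods
# ---------------------------------------------------------------------------

def infer_correlation(expr: ExpressionMatrix, flavor: str = "pearson") -> ConfidenceMatrix:
    """Absolute Pearson or Spearman correlation between gene profiles."""
    _require_samples(expr, 3, "correlation")
    _check_variance(expr)
    X = expr.matrix()
    if flavor == "pearson":
        corr = np.corrcoef(X)
    elif flavor == "spearman":
        corr, _ = spearmanr(X.T)
        if np.ndim(corr) == 0:  # scipy collapses the 2-gene case to a scalar
            corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])
    else:
        raise ValueError(f"unknown correlation flavor {flavor!r}")
    values = np.abs(np.nan_to_num(corr, nan=0.0))
    np.fill_diagonal(values, 0.0)
    return ConfidenceMatrix(expr.genes, values, directed=False)


def infer_tree_ensemble(
    expr: ExpressionMatrix, n_trees: int = 100, seed: int = 0
) -> ConfidenceMatrix:
    """Per-target regression-tree-ensemble importances (GENIE3-style).

    Each gene in turn is regressed on all others with an extremely
    randomized trees ensemble; the regulators' impurity importances,
    normalized to sum one per target, are the directed confidences.
    """
    from sklearn.ensemble import ExtraTreesRegressor

    _require_samples(expr, 5, "tree-ensemble inference")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X = expr.matrix()
    genes = expr.genes
    n = len(genes)
    values = np.zeros((n, n))
    for t in range(n):
        predictors = [i for i in range(n) if i != t]
        model = ExtraTreesRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=(seed + t) % (2**31 - 1),
        )
        model.fit(X[predictors].T, X[t])
        imp = model.feature_importances_
        s = imp.sum()
        if s > 0:
            imp = imp / s
        for k, r in enumerate(predictors):
            values[r, t] = imp[k]
    return ConfidenceMatrix(genes, values, directed=True)


def _stability_selection(
    expr: ExpressionMatrix,
    penalty_factors: np.ndarray | None,
    n_resamples: int,
    selection_fraction: float,
    n_select: int,
    reweight_low: float,
    seed: int,
) -> ConfidenceMatrix:
    """Selection frequencies of regulators over randomized LARS runs.

    ``penalty_factors`` (regulators × targets, >= 1) divide each
    regulator's effective sparsity penalty: a factor of f is applied by
    scaling the predictor column by f, the adaptive-lasso identity.
    """
    from sklearn.linear_model import lars_path

    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    X = _standardize(expr.matrix())
    genes = expr.genes
    n_genes, n_samples = X.shape
    half = max(2, int(math.floor(n_samples * selection_fraction)))
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_genes, n_genes))
    max_steps = min(n_select, n_genes - 1)
    for t in range(n_genes):
        predictors = np.array([i for i in range(n_genes) if i != t])
        pf = (
            penalty_factors[predictors, t]
            if penalty_factors is not None
            else np.ones(len(predictors))
        )
        for _ in range(n_resamples):
            subset = rng.choice(n_samples, size=half, replace=False)
            w = rng.uniform(reweight_low, 1.0, size=len(predictors))
            Xs = X[np.ix_(predictors, subset)].T * (w * pf)
            y = X[t, subset]
            try:
                _, active, _ = lars_path(Xs, y, method="lar", max_iter=max_steps)
            except Exception:
                continue
            for k in active[:max_steps]:
                counts[predictors[k], t] += 1
    return ConfidenceMatrix(genes, counts / n_resamples, directed=True)


def infer_stability_regression(
    expr: ExpressionMatrix,
    n_resamples: int = 50,
    selection_fraction: float = 0.5,
    seed: int = 0,
    n_select: int = 5,
    reweight_low: float = 0.3,
) -> ConfidenceMatrix:
    """TIGRESS-style stability selection: per target, the frequency with
    which each regulator enters a sparse LARS model across half-sample
    resamples with random predictor reweighting."""
    return _stability_selection(
        expr, None, n_resamples, selection_fraction, n_select, reweight_low, seed
    )


# ---------------------------------------------------------------------------
# Information-theoretic methods
# ---------------------------------------------------------------------------

def infer_mutual_information(
    expr: ExpressionMatrix, n_bins: int | None = None
) -> ConfidenceMatrix:
    """Plug-in mutual information (bits) on equal-frequency bins."""
    return ConfidenceMatrix(expr.genes, _mi_matrix(expr, n_bins), directed=False)


def infer_clr(expr: ExpressionMatrix, n_bins: int | None = None) -> ConfidenceMatrix:
    """Context-likelihood-of-relatedness: each MI value is z-scored against
    both genes' background MI distributions; negative z-scores clip to 0."""
    mi = _mi_matrix(expr, n_bins)
    n = mi.shape[0]
    z = np.zeros_like(mi)
    for i in range(n):
        background = np.delete(mi[i], i)
        mu, sd = background.mean(), background.std()
        for j in range(n):
            if j == i:
                continue
            z[i, j] = (mi[i, j] - mu) / sd if sd > 0 else 0.0
    zi = np.maximum(z, 0.0)
    values = np.sqrt(zi**2 + zi.T**2)
    return ConfidenceMatrix(expr.genes, values, directed=False)


def infer_aracne(
    expr: ExpressionMatrix, n_bins: int | None = None, dpi_tolerance: float = 0.15
) -> ConfidenceMatrix:
    """MI matrix pruned by the data-processing inequality: in every gene
    triangle the weakest edge is zeroed when it is weaker than
    (1 − tolerance) times the smaller of the other two."""
    if dpi_tolerance < 0:
        raise ValueError("dpi_tolerance must be >= 0")
    mi = _mi_matrix(expr, n_bins)
    n = mi.shape[0]
    remove: set[tuple[int, int]] = set()
    for i, j, k in itertools.combinations(range(n), 3):
        edges = [((i, j), mi[i, j]), ((i, k), mi[i, k]), ((j, k), mi[j, k])]
        edges.sort(key=lambda kv: kv[1])
        weakest, w = edges[0]
        if w < (1.0 - dpi_tolerance) * edges[1][1]:
            remove.add(weakest)
    pruned = mi.copy()
    for i, j in remove:
        pruned[i, j] = pruned[j, i] = 0.0
    return ConfidenceMatrix(expr.genes, pruned, directed=False)


def infer_mrnetb(expr: ExpressionMatrix, n_bins: int | None = None) -> ConfidenceMatrix:
    """Maximum-relevance / minimum-redundancy scoring (MRNET-family).

    Per target, regulators are greedily added in order of relevance minus
    mean redundancy with the already-selected set; each regulator's score is
    its criterion value at selection time.  The pairwise confidence is the
    larger of the two directed scores, floored at zero.
    """
    mi = _mi_matrix(expr, n_bins)
    n = mi.shape[0]
    directed = np.full((n, n), -np.inf)
    for t in range(n):
        remaining = [i for i in range(n) if i != t]
        selected: list[int] = []
        while remaining:
            best, best_u = None, -np.inf
            for r in remaining:
                redundancy = np.mean([mi[r, s] for s in selected]) if selected else 0.0
                u = mi[r, t] - redundancy
                if u > best_u:
                    best, best_u = r, u
            directed[best, t] = best_u
            selected.append(best)
            remaining.remove(best)
    values = np.maximum(np.maximum(directed, directed.T), 0.0)
    np.fill_diagonal(values, 0.0)
    return ConfidenceMatrix(expr.genes, values, directed=False)


# ---------------------------------------------------------------------------
# Probabilistic methods
# ---------------------------------------------------------------------------

def partial_correlation_from_covariance(cov: np.ndarray) -> np.ndarray:
    """|partial correlation| matrix from a covariance matrix (via its inverse)."""
    precision = np.linalg.inv(cov)
    d = np.sqrt(np.diag(precision))
    pcor = -precision / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return np.abs(pcor)


def infer_partial_correlation(expr: ExpressionMatrix) -> ConfidenceMatrix:
    """Gaussian-graphical-model confidences: absolute partial correlations
    from a Ledoit–Wolf shrinkage-regularized covariance matrix."""
    from sklearn.covariance import LedoitWolf

    _require_samples(expr, 4, "partial correlation")
    X = expr.matrix()
    lw = LedoitWolf().fit(X.T)
    try:
        values = partial_correlation_from_covariance(lw.covariance_)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance not invertible after shrinkage") from exc
    return ConfidenceMatrix(expr.genes, values, directed=False)


def _bdeu_local_score(
    target_bins: np.ndarray, parent_bins: list[np.ndarray], n_bins: int, ess: float = 1.0
) -> float:
    """Bayesian-Dirichlet (BDeu) local score of target given its parents."""
    n_samples = len(target_bins)
    if parent_bins:
        config = np.zeros(n_samples, dtype=np.int64)
        q = 1
        for pb in parent_bins:
            config = config * n_bins + pb
            q *= n_bins
    else:
        config = np.zeros(n_samples, dtype=np.int64)
        q = 1
    key = config * n_bins + target_bins
    _, njk = np.unique(key, return_counts=True)
    _, nj = np.unique(config, return_counts=True)
    a_j = ess / q
    a_jk = ess / (q * n_bins)
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + nj))
        + np.sum(gammaln(a_jk + njk) - gammaln(a_jk))
    )
    return score


def infer_bayesian_score(
    expr: ExpressionMatrix,
    n_bins: int | None = None,
    max_parents: int = 2,
    seed: int = 0,
) -> ConfidenceMatrix:
    """Exhaustive Bayesian parent-set scoring on discretized data.

    For each target every parent set up to ``max_parents`` regulators is
    scored with a BDeu metric; the confidence of edge r→t is the
    posterior-weighted frequency of parent sets containing r.  Exhaustive
    enumeration is exponential, so the gene set is capped at 15; use the
    other methods for larger problems.
    """
    genes = expr.genes
    if len(genes) > 15:
        raise ValueError(
            "exhaustive Bayesian scoring is limited to <= 15 genes; "
            "use the correlation/MI/tree methods for larger gene sets"
        )
    if max_parents > 3:
        raise ValueError("max_parents must be <= 3")
    n_bins = default_n_bins(expr.n_samples) if n_bins is None else n_bins
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    _require_samples(expr, n_bins, "Bayesian scoring")
    X = expr.matrix()
    binned = [equal_frequency_bins(X[i], n_bins) for i in range(len(genes))]
    n = len(genes)
    values = np.zeros((n, n))
    for t in range(n):
        others = [i for i in range(n) if i != t]
        sets = []
        scores = []
        for size in range(0, max_parents + 1):
            for parents in itertools.combinations(others, size):
                sets.append(parents)
                scores.append(
                    _bdeu_local_score(binned[t], [binned[p] for p in parents], n_bins)
                )
        scores = np.array(scores)
        weights = np.exp(scores - scores.max())
        weights /= weights.sum()
        for parents, w in zip(sets, weights):
            for p in parents:
                values[p, t] += w
    return ConfidenceMatrix(genes, values, directed=True)


# ---------------------------------------------------------------------------
# Method registry and consensus
# ---------------------------------------------------------------------------

#: method name -> (callable, takes_seed)
METHOD_REGISTRY = {
    "pearson": (lambda expr, seed=None, **kw: infer_correlation(expr, "pearson"), False),
    "spearman": (lambda expr, seed=None, **kw: infer_correlation(expr, "spearman"), False),
    "mi": (lambda expr, seed=None, **kw: infer_mutual_information(expr, **kw), False),
    "clr": (lambda expr, seed=None, **kw: infer_clr(expr, **kw), False),
    "aracne": (lambda expr, seed=None, **kw: infer_aracne(expr, **kw), False),
    "mrnetb": (lambda expr, seed=None, **kw: infer_mrnetb(expr, **kw), False),
    "genie3": (lambda expr, seed=0, **kw: infer_tree_ensemble(expr, seed=seed, **kw), True),
    "tigress": (
        lambda expr, seed=0, **kw: infer_stability_regression(expr, seed=seed, **kw),
        True,
    ),
    "ggm": (lambda expr, seed=None, **kw: infer_partial_correlation(expr), False),
    "bayes": (lambda expr, seed=0, **kw: infer_bayesian_score(expr, seed=seed, **kw), True),
}


def run_method(name: str, expr: ExpressionMatrix, seed: int = 0, **params) -> MethodResult:
    if name not in METHOD_REGISTRY:
        raise ValueError(f"unknown method {name!r}; known: {sorted(METHOD_REGISTRY)}")
    fn, takes_seed = METHOD_REGISTRY[name]
    conf = fn(expr, seed=seed, **params)
    return MethodResult(name, conf, seed=seed if takes_seed else None)


def consensus_rank(results: Sequence[MethodResult]) -> RankedEdgeList:
    """Average-rank voting over methods (undirected consensus).

    Every method's ranking is collapsed to undirected pairs and converted to
    average ranks; a pair missing from a method's list is charged that
    method's worst rank.  Pairs are sorted ascending by mean rank with
    lexicographic tie-break; the returned scores are the negated mean ranks
    (so better pairs carry higher scores).
    """
    if len(results) < 2:
        raise ValueError("consensus requires at least two method results")
    node_sets = [frozenset(r.confidence.node_order) for r in results]
    if len(set(node_sets)) != 1:
        raise ValueError("all method results must cover the same node set")
    nodes = sorted(node_sets[0])
    universe = [canonical_pair(a, b) for a, b in itertools.combinations(nodes, 2)]
    worst = float(len(universe))
    mean_ranks: dict[tuple[str, str], float] = {p: 0.0 for p in universe}
    for result in results:
        undirected = collapse_undirected(result.ranking)
        ranks = {e.pair: e.rank for e in undirected.entries}
        for p in universe:
            mean_ranks[p] += ranks.get(p, worst)
    k = len(results)
    scored = {p: -(total / k) for p, total in mean_ranks.items()}
    return ranked_list_from_scores(scored, "undirected")


def consensus_mean_ranks(consensus: RankedEdgeList) -> dict[tuple[str, str], float]:
    """Recover mean ranks from a consensus ranking (scores are −mean rank)."""
    return {e.pair: -e.score for e in consensus.entries}
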