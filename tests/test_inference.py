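import itertools
import math

import numpy as np
import pandas as pd
import pytest

from chondronet import (
    ConfidenceMatrix,
    ExpressionMatrix,
    MethodResult,
    consensus_mean_ranks,
    consensus_rank,
    infer_aracne,
    infer_bayesian_score,
    infer_clr,
    infer_correlation,
    infer_mrnetb,
    infer_mutual_information,
    infer_partial_correlation,
    infer_stability_regression,
    infer_tree_ensemble,
    ranked_list_from_scores,
)
from chondronet.inference import (
    equal_frequency_bins,
    mutual_information_bits,
    partial_correlation_from_covariance,
)
from conftest import chain_expression


def expr_from_rows(rows: dict) -> ExpressionMatrix:
    n = len(next(iter(rows.values())))
    return ExpressionMatrix(
        pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T
    )


class TestCorrelation:
    def test_exact_linear_dependence(self):
        expr = expr_from_rows({"A": [1, 2, 3, 4], "B": [2, 4, 6, 8]})
        conf = infer_correlation(expr, "pearson")
        assert conf.score("A", "B") == pytest.approx(1.0)

    def test_constructed_orthogonality(self):
        expr = expr_from_rows({"A": [1, -1, 1, -1], "B": [1, 1, -1, -1]})
        conf = infer_correlation(expr, "pearson")
        assert conf.score("A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_four_samples(self):
        # r = 3.5 / sqrt(8.75 * 5) = 0.5291502622129181
        expr = expr_from_rows({"A": [1, 2, 3, 5], "B": [2, 1, 4, 3]})
        conf = infer_correlation(expr, "pearson")
        assert conf.score("A", "B") == pytest.approx(0.5291502622129181)

    def test_spearman_monotone_transform_invariant(self):
        a = [0.1, 0.5, 1.2, 2.0, 3.3]
        expr = expr_from_rows({"A": a, "B": [math.exp(x) for x in a]})
        conf = infer_correlation(expr, "spearman")
        assert conf.score("A", "B") == pytest.approx(1.0)

    def test_zero_variance_gene_named(self):
        expr = expr_from_rows({"A": [1, 2, 3], "FLAT": [5, 5, 5]})
        with pytest.raises(ValueError, match="FLAT"):
            infer_correlation(expr)

    def test_too_few_samples(self):
        expr = expr_from_rows({"A": [1, 2], "B": [2, 1]})
        with pytest.raises(ValueError, match="at least 3"):
            infer_correlation(expr)


class TestMutualInformation:
    def test_identical_fair_binary_profile_is_one_bit(self):
        expr = expr_from_rows({"A": [0, 0, 1, 1], "B": [0, 0, 1, 1]})
        conf = infer_mutual_information(expr, n_bins=2)
        assert conf.score("A", "B") == pytest.approx(1.0)

    def test_independent_patterns_zero_bits(self):
        bx = np.array([0, 0, 1, 1])
        by = np.array([0, 1, 0, 1])
        assert mutual_information_bits(bx, by) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_plug_in_formula(self):
        bx = np.array([0, 0, 0, 1, 1, 1])
        by = np.array([0, 0, 1, 0, 1, 1])
        # brute force over the joint count table
        expected = 0.0
        n = len(bx)
        for vx in (0, 1):
            for vy in (0, 1):
                nxy = int(np.sum((bx == vx) & (by == vy)))
                if nxy == 0:
                    continue
                p = nxy / n
                px = np.sum(bx == vx) / n
                py = np.sum(by == vy) / n
                expected += p * math.log2(p / (px * py))
        assert mutual_information_bits(bx, by) == pytest.approx(expected)

    def test_symmetry_exact(self, toy_expression):
        conf = infer_mutual_information(toy_expression, n_bins=3)
        assert np.array_equal(conf.values, conf.values.T)

    def test_degenerate_binning_rejected(self):
        with pytest.raises(ValueError, match="one bin"):
            equal_frequency_bins(np.array([1.0, 1.0, 1.0, 1.0]), 2)


class TestCLR:
    def test_matches_step_by_step_recomputation(self, toy_expression):
        mi = infer_mutual_information(toy_expression, n_bins=3).values
        conf = infer_clr(toy_expression, n_bins=3)
        n = mi.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                bg_i = np.delete(mi[i], i)
                bg_j = np.delete(mi[j], j)
                zi = (mi[i, j] - bg_i.mean()) / bg_i.std() if bg_i.std() > 0 else 0.0
                zj = (mi[i, j] - bg_j.mean()) / bg_j.std() if bg_j.std() > 0 else 0.0
                expected = math.sqrt(max(0.0, zi) ** 2 + max(0.0, zj) ** 2)
                assert conf.values[i, j] == pytest.approx(expected)

    def test_uniquely_strong_pair_ranks_first(self, toy_expression):
        conf = infer_clr(toy_expression, n_bins=3)
        ranking = conf.to_ranked_edge_list()
        assert ranking.entries[0].pair == ("A", "B")


class TestAracne:
    def test_chain_indirect_edge_pruned_at_zero_tolerance(self):
        expr = chain_expression(120, seed=5)
        mi = infer_mutual_information(expr).values
        conf = infer_aracne(expr, dpi_tolerance=0.0)
        # (A, C) is the triangle's weakest edge and must be zeroed
        assert mi[0, 2] == min(mi[0, 1], mi[0, 2], mi[1, 2])
        assert conf.score("A", "C") == 0.0
        assert conf.score("A", "B") > 0.0
        assert conf.score("B", "C") > 0.0

    def test_tolerance_one_disables_pruning(self):
        expr = chain_expression(120, seed=5)
        mi = infer_mutual_information(expr)
        conf = infer_aracne(expr, dpi_tolerance=1.0)
        assert np.array_equal(conf.values, mi.values)

    def test_never_exceeds_mi(self, toy_expression):
        mi = infer_mutual_information(toy_expression).values
        pruned = infer_aracne(toy_expression).values
        assert (pruned <= mi + 1e-12).all()

    def test_strong_disconnected_pairs_survive(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=100)
        c = rng.normal(size=100)
        expr = expr_from_rows(
            {
                "A": a,
                "B": a + rng.normal(scale=0.05, size=100),
                "C": c,
                "D": c + rng.normal(scale=0.05, size=100),
            }
        )
        conf = infer_aracne(expr, dpi_tolerance=0.0)
        assert conf.score("A", "B") > 0.0
        assert conf.score("C", "D") > 0.0


class TestMrnetb:
    def test_two_genes_score_equals_mi(self):
        expr = expr_from_rows({"A": [1, 2, 3, 4, 5, 6], "B": [1, 2, 3, 4, 6, 5]})
        mi = infer_mutual_information(expr, n_bins=2)
        conf = infer_mrnetb(expr, n_bins=2)
        assert conf.score("A", "B") == pytest.approx(mi.score("A", "B"))

    def test_redundant_duplicate_scores_no_higher(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=60)
        expr = expr_from_rows(
            {"T": a + rng.normal(scale=0.2, size=60), "R": a, "R2": a}
        )
        conf = infer_mrnetb(expr, n_bins=3)
        first = max(conf.score("R", "T"), conf.score("R2", "T"))
        second = min(conf.score("R", "T"), conf.score("R2", "T"))
        assert second <= first

    def test_matches_step_by_step_mrmr_arithmetic(self):
        expr = chain_expression(80, seed=9)
        mi = infer_mutual_information(expr, n_bins=3).values
        conf = infer_mrnetb(expr, n_bins=3)
        genes = expr.genes
        directed = np.full((3, 3), -np.inf)
        for t in range(3):
            remaining = [i for i in range(3) if i != t]
            selected = []
            while remaining:
                scores = {
                    r: mi[r, t]
                    - (np.mean([mi[r, s] for s in selected]) if selected else 0.0)
                    for r in remaining
                }
                best = max(remaining, key=lambda r: scores[r])
                directed[best, t] = scores[best]
                selected.append(best)
                remaining.remove(best)
        expected = np.maximum(np.maximum(directed, directed.T), 0.0)
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(conf.values, expected)


class TestTreeEnsemble:
    def test_dominant_predictor_ranks_highest(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=40)
        expr = expr_from_rows(
            {
                "T": t,
                "R": t,
                "N1": rng.normal(size=40),
                "N2": rng.normal(size=40),
            }
        )
        conf = infer_tree_ensemble(expr, n_trees=50, seed=1)
        col = {g: conf.score(g, "T") for g in ("R", "N1", "N2")}
        assert col["R"] == max(col.values())

    def test_single_candidate_regulator_gets_full_importance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=20)
        expr = expr_from_rows({"A": a, "B": a + rng.normal(scale=0.1, size=20)})
        conf = infer_tree_ensemble(expr, n_trees=20, seed=0)
        assert conf.score("A", "B") == pytest.approx(1.0)
        assert conf.score("B", "A") == pytest.approx(1.0)

    def test_bit_reproducible_under_seed(self, toy_expression):
        a = infer_tree_ensemble(toy_expression, n_trees=25, seed=9)
        b = infer_tree_ensemble(toy_expression, n_trees=25, seed=9)
        assert np.array_equal(a.values, b.values)


class TestStabilityRegression:
    def test_perfect_regulator_always_selected(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=40)
        expr = expr_from_rows(
            {"T": a, "R": a, "N1": rng.normal(size=40), "N2": rng.normal(size=40)}
        )
        conf = infer_stability_regression(expr, n_resamples=20, seed=3)
        assert conf.score("R", "T") == pytest.approx(1.0)

    def test_pure_noise_low_frequency_at_stringent_sparsity(self):
        freqs = []
        for seed in range(1, 21):
            rng = np.random.default_rng(1000 + seed)
            expr = expr_from_rows(
                {f"G{i}": rng.normal(size=30) for i in range(8)}
            )
            conf = infer_stability_regression(
                expr, n_resamples=10, seed=seed, n_select=1
            )
            off_diag = ~np.eye(8, dtype=bool)
            freqs.append(conf.values[off_diag].mean())
        # with one selection slot and 7 interchangeable noise regulators,
        # mean selection frequency stays near 1/7, far below confident levels
        assert np.mean(freqs) < 0.2

    def test_bit_reproducible_under_seed(self, toy_expression):
        a = infer_stability_regression(toy_expression, n_resamples=15, seed=5)
        b = infer_stability_regression(toy_expression, n_resamples=15, seed=5)
        assert np.array_equal(a.values, b.values)


class TestPartialCorrelation:
    def test_chain_conditional_independence(self):
        expr = chain_expression(200, seed=21)
        raw = infer_correlation(expr, "pearson")
        pcor = infer_partial_correlation(expr)
        assert raw.score("A", "C") > 0.5
        assert pcor.score("A", "C") < 0.1

    def test_two_gene_case_approaches_pearson(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=500)
        b = 0.7 * a + rng.normal(scale=0.5, size=500)
        expr = expr_from_rows({"A": a, "B": b})
        raw = infer_correlation(expr, "pearson")
        pcor = infer_partial_correlation(expr)
        # no conditioning set: shrinkage is the only (small-sample) difference
        assert pcor.score("A", "B") == pytest.approx(raw.score("A", "B"), abs=0.05)

    def test_identity_covariance_gives_zeros(self):
        values = partial_correlation_from_covariance(np.eye(4))
        assert np.allclose(values, 0.0)


class TestBayesianScore:
    def test_dependent_pair_outranks_independent(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=80)
        expr = expr_from_rows(
            {"A": a, "B": a + rng.normal(scale=0.3, size=80), "C": rng.normal(size=80)}
        )
        conf = infer_bayesian_score(expr, max_parents=1)
        dependent = conf.score("A", "B") + conf.score("B", "A")
        independent = conf.score("A", "C") + conf.score("C", "A")
        assert dependent > independent

    def test_independent_genes_low_confidence(self):
        rng = np.random.default_rng(500)
        expr = expr_from_rows({f"G{i}": rng.normal(size=500) for i in range(4)})
        conf = infer_bayesian_score(expr, max_parents=1)
        assert conf.values.max() < 0.1

    def test_zero_max_parents_gives_empty_network(self, toy_expression):
        conf = infer_bayesian_score(toy_expression, max_parents=0)
        assert not conf.values.any()

    def test_large_gene_sets_rejected(self):
        rng = np.random.default_rng(0)
        expr = expr_from_rows({f"G{i}": rng.normal(size=10) for i in range(16)})
        with pytest.raises(ValueError, match="15 genes"):
            infer_bayesian_score(expr)


class TestConsensus:
    @staticmethod
    def method(name, scores, nodes=("A", "B", "C")):
        nodes = list(nodes)
        values = np.zeros((len(nodes), len(nodes)))
        for (a, b), s in scores.items():
            i, j = nodes.index(a), nodes.index(b)
            values[i, j] = values[j, i] = s
        return MethodResult(name, ConfidenceMatrix(nodes, values, directed=False))

    def test_identical_rankings_fixed_point(self):
        scores = {("A", "B"): 0.9, ("A", "C"): 0.5, ("B", "C"): 0.1}
        m1 = self.method("m1", scores)
        m2 = self.method("m2", scores)
        cons = consensus_rank([m1, m2])
        assert [e.pair for e in cons.entries] == [
            e.pair for e in m1.ranking.entries
        ]

    def test_hand_averaged_three_pairs(self):
        m1 = self.method("m1", {("A", "B"): 3, ("A", "C"): 2, ("B", "C"): 1})
        m2 = self.method("m2", {("A", "C"): 3, ("A", "B"): 2, ("B", "C"): 1})
        cons = consensus_rank([m1, m2])
        ranks = consensus_mean_ranks(cons)
        assert ranks[("A", "B")] == pytest.approx(1.5)
        assert ranks[("A", "C")] == pytest.approx(1.5)
        assert ranks[("B", "C")] == pytest.approx(3.0)
        # lexicographic tie-break puts AB before AC
        assert [e.pair for e in cons.entries] == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_missing_pair_gets_worst_rank(self):
        m1 = self.method("m1", {("A", "B"): 0.9, ("A", "C"): 0.5, ("B", "C"): 0.1})
        partial = MethodResult(
            "partial",
            self.method("x", {("A", "B"): 0.9, ("A", "C"): 0.5, ("B", "C"): 0.1}).confidence,
            ranking=ranked_list_from_scores({("A", "B"): 1.0}, "undirected"),
        )
        cons = consensus_rank([m1, partial])
        ranks = consensus_mean_ranks(cons)
        # partial charges worst rank (3) for the two unlisted pairs
        assert ranks[("A", "C")] == pytest.approx((2 + 3) / 2)
        assert ranks[("B", "C")] == pytest.approx((3 + 3) / 2)

    def test_order_invariance(self):
        m1 = self.method("m1", {("A", "B"): 3, ("A", "C"): 2, ("B", "C"): 1})
        m2 = self.method("m2", {("A", "C"): 3, ("A", "B"): 2, ("B", "C"): 1})
        m3 = self.method("m3", {("B", "C"): 3, ("A", "B"): 2, ("A", "C"): 1})
        assert consensus_rank([m1, m2, m3]) == consensus_rank([m3, m1, m2])

    def test_monotone_rescaling_invariance(self):
        base = {("A", "B"): 0.9, ("A", "C"): 0.5, ("B", "C"): 0.1}
        rescaled = {k: math.exp(5 * v) for k, v in base.items()}
        m1 = self.method("m1", base)
        m2 = self.method("m2", {("A", "C"): 0.8, ("A", "B"): 0.3, ("B", "C"): 0.2})
        assert consensus_rank([m1, m2]) == consensus_rank(
            [self.method("m1", rescaled), m2]
        )

    def test_mismatched_node_sets_rejected(self):
        m1 = self.method("m1", {("A", "B"): 1.0}, nodes=("A", "B"))
        m2 = self.method("m2", {("A", "C"): 1.0}, nodes=("A", "C"))
        with pytest.raises(ValueError, match="node set"):
            consensus_rank([m1, m2])

    def test_fewer_than_two_methods_rejected(self):
        m1 = self.method("m1", {("A", "B"): 1.0})
        with pytest.raises(ValueError):
            consensus_rank([m1])


@pytest.mark.parametrize(
    "method",
    [
        lambda e: infer_correlation(e, "pearson"),
        lambda e: infer_correlation(e, "spearman"),
        lambda e: infer_mutual_information(e, n_bins=3),
        lambda e: infer_clr(e, n_bins=3),
        lambda e: infer_aracne(e, n_bins=3),
        lambda e: infer_mrnetb(e, n_bins=3),
        lambda e: infer_partial_correlation(e),
    ],
)
def test_undirected_outputs_are_symmetric_finite_nonnegative(toy_expression, method):
    conf = method(toy_expression)
    assert not conf.directed
    assert np.array_equal(conf.values, conf.values.T)
    assert np.isfinite(conf.values).all()
    assert (conf.values >= 0).all()
    assert np.diag(conf.values).sum() == 0.0
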