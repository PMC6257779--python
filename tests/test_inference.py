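"""Two-stage conditional-dependence inference against independent OLS oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from lagnet import (
    ExpressionSeries,
    InsufficientDataError,
    ParameterError,
    RegulatoryNetwork,
    build_transitions,
    generate_ground_truth,
    infer_network,
    prune_step2,
    score_step1,
    simulate_expression,
    threshold_step1,
)
from lagnet._ols import ols_coef_pvalues


def _series(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    ids = tuple(gene_ids) if gene_ids else tuple(f"g{k}" for k in range(values.shape[0]))
    return ExpressionSeries(ids, tuple(range(values.shape[1])), values)


def _max_pvalue_oracle(L, Y, i, j, exclude_self=True):
    """Worst-case single-conditioner p-value via statsmodels, pair by pair."""
    p = L.shape[0]
    best = None
    for z in range(p):
        if z == j or (exclude_self and z == i):
            continue
        X = sm.add_constant(np.column_stack([L[j], L[z]]))
        best = max(best or 0.0, float(sm.OLS(Y[i], X).fit().pvalues[1]))
    if best is None:  # no conditioner available: simple regression
        X = sm.add_constant(L[j])
        best = float(sm.OLS(Y[i], X).fit().pvalues[1])
    return best


class TestBuildTransitions:
    def test_t11_series_yields_10_transitions(self):
        series = _series(np.arange(33).reshape(3, 11))
        assert build_transitions(series).n_transitions == 10

    def test_columns_are_consecutive_pairs(self):
        series = _series([[1.0, 2.0, 3.0]])
        tr = build_transitions(series)
        assert np.array_equal(tr.predictors, [[1.0, 2.0]])
        assert np.array_equal(tr.responses, [[2.0, 3.0]])


class TestScoreStep1:
    def test_all_zero_series_scores_one_everywhere(self):
        tr = build_transitions(_series(np.zeros((4, 8))))
        sc = score_step1(tr)
        off_diag = ~np.eye(4, dtype=bool)
        assert np.all(sc.s1[off_diag] == 1.0)
        assert np.all(np.isnan(np.diag(sc.s1)))

    def test_matches_statsmodels_max_over_conditioners(self, rng):
        """Every scored entry equals the brute-force statsmodels max-p oracle
        to 10 significant digits, on 25 random instances."""
        for _ in range(25):
            p = int(rng.integers(3, 6))
            n = int(rng.integers(6, 15))
            L = rng.standard_normal((p, n))
            Y = 0.5 * L[::-1] + rng.standard_normal((p, n))
            ids = tuple(f"g{k}" for k in range(p))
            from lagnet.inference import TransitionSet

            tr = TransitionSet(ids, L, Y)
            sc = score_step1(tr)
            for i in range(p):
                for j in range(p):
                    if i == j:
                        continue
                    oracle = _max_pvalue_oracle(L, Y, i, j)
                    assert sc.s1[i, j] == pytest.approx(oracle, rel=1e-10)

    def test_signal_edge_scores_far_below_null_edges(self):
        truth = np.zeros((3, 3))
        truth[1, 0] = 0.9  # a -> b
        rng = np.random.default_rng(42)
        x = np.zeros((3, 30))
        x[:, 0] = rng.standard_normal(3)
        for k in range(1, 30):
            x[:, k] = truth @ x[:, k - 1] + rng.normal(0, 0.05, 3)
        sc = score_step1(build_transitions(_series(x, "abc")))
        assert sc.s1[1, 0] < 1e-4  # b's dependence on lagged a
        assert sc.s1[0, 1] > 0.05  # no reverse edge

    def test_null_rate_is_conservative(self):
        """On independent noise the max-over-conditioners score rejects at
        most ~alpha of pairs at alpha=0.05 (the max inflates p-values)."""
        rng = np.random.default_rng(7)
        hits = total = 0
        for _ in range(500):
            x = rng.standard_normal((3, 30))
            sc = score_step1(build_transitions(_series(x)))
            vals = sc.s1[~np.isnan(sc.s1)]
            hits += int(np.sum(vals < 0.05))
            total += vals.size
        se = np.sqrt(0.05 * 0.95 / total)
        assert hits / total <= 0.05 + 3 * se

    def test_pre_max_pvalues_are_uniform_under_null(self):
        """The underlying per-regression p-value is a genuine p-value:
        uniform on [0, 1] under independence (KS test, 2000 replicates)."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(2000):
            X = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
            y = rng.standard_normal(20)
            pvals.append(ols_coef_pvalues(X, y)[1][1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_too_few_transitions_rejected(self):
        with pytest.raises(InsufficientDataError):
            score_step1(build_transitions(_series(np.random.rand(3, 4))))


class TestThresholdStep1:
    @pytest.fixture
    def scores(self, rng):
        tr = build_transitions(_series(rng.standard_normal((4, 10))))
        return score_step1(tr)

    def test_alpha_one_keeps_every_scored_pair(self, scores):
        net = threshold_step1(scores, 1.0)
        assert net.n_edges == 4 * 3

    def test_alpha_below_minimum_gives_empty_network(self, scores):
        tiny = np.nanmin(scores.s1) / 2
        assert threshold_step1(scores, tiny).n_edges == 0

    def test_edge_sets_are_monotone_in_alpha(self, scores):
        nets = [threshold_step1(scores, a).edge_set for a in (0.05, 0.2, 0.5, 1.0)]
        for small, large in zip(nets, nets[1:]):
            assert small <= large

    def test_invalid_alpha_rejected(self, scores):
        for alpha in (0.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                threshold_step1(scores, alpha)


class TestPruneStep2:
    def test_single_parent_matches_simple_regression_oracle(self, rng):
        from lagnet.inference import TransitionSet

        for _ in range(10):
            L = rng.standard_normal((3, 12))
            Y = rng.standard_normal((3, 12))
            ids = ("a", "b", "c")
            tr = TransitionSet(ids, L, Y)
            candidate = RegulatoryNetwork(ids, {("a", "b"): 0.1})
            pruned = prune_step2(tr, candidate, alpha2=1.0)
            X = sm.add_constant(L[0])
            oracle = float(sm.OLS(Y[1], X).fit().pvalues[1])
            assert pruned.edges[("a", "b")] == pytest.approx(oracle, rel=1e-10)

    def test_empty_candidate_returns_empty_network(self, rng):
        from lagnet.inference import TransitionSet

        tr = TransitionSet(("a", "b"), rng.standard_normal((2, 8)),
                           rng.standard_normal((2, 8)))
        assert prune_step2(tr, RegulatoryNetwork(("a", "b")), 0.05).n_edges == 0

    def test_alpha_one_keeps_candidate_unchanged(self, rng):
        from lagnet.inference import TransitionSet

        L = rng.standard_normal((4, 12))
        Y = rng.standard_normal((4, 12))
        ids = tuple("abcd")
        tr = TransitionSet(ids, L, Y)
        candidate = RegulatoryNetwork(ids, {("a", "b"): 0.1, ("c", "d"): 0.2})
        assert prune_step2(tr, candidate, 1.0).edge_set == candidate.edge_set


class TestInferNetwork:
    def test_all_zero_series_gives_empty_network(self):
        assert infer_network(_series(np.zeros((5, 11)))).n_edges == 0

    def test_composition_equals_manual_stages(self, rng):
        truth = generate_ground_truth(8, 10, seed=21)
        series = simulate_expression(truth, range(20), seed=22)
        direct = infer_network(series, alpha1=0.4, alpha2=0.1)
        tr = build_transitions(series)
        manual = prune_step2(tr, threshold_step1(score_step1(tr), 0.4), 0.1)
        assert direct.edge_set == manual.edge_set
        assert direct.edges == manual.edges

    def test_cycles_are_representable(self):
        """The lag-1 formulation allows directed cycles in the result."""
        rng = np.random.default_rng(5)
        coeff = np.zeros((2, 2))
        coeff[1, 0] = 0.9
        coeff[0, 1] = -0.9
        x = np.zeros((2, 40))
        x[:, 0] = [1.0, 0.5]
        for k in range(1, 40):
            x[:, k] = coeff @ x[:, k - 1] + rng.normal(0, 0.05, 2)
        net = infer_network(_series(x, "ab"))
        assert {("a", "b"), ("b", "a")} <= net.edge_set
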