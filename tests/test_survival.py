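"""Discrete-time survival machinery: closed forms, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graphsurv.autodiff import Tensor
from graphsurv.errors import ConfigurationError, UndefinedMetricError
from graphsurv.survival import (BinEdges, LossWeights, SurvivalRecord,
                                concordance_index, discretize, fit_bins,
                                hazards, nll_loss, risk_score, survival_probs,
                                time_dependent_auc)
from oracles import oracle_cindex


class TestFitBins:
    def test_quartiles_of_one_to_eight(self):
        # type-7 quantiles of {1..8}: 2.75 / 4.5 / 6.25 (sort-and-interpolate)
        times = np.arange(1.0, 9.0)
        edges = fit_bins(times, 4, events=np.ones(8, int))
        np.testing.assert_allclose(edges.cut_points, [2.75, 4.5, 6.25])
        assert edges.n_bins == 4
        assert edges.full_edges[0] == 0.0 and edges.full_edges[-1] == np.inf

    def test_identical_times_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_bins(np.full(10, 5.0), 4, events=np.ones(10, int))

    def test_two_bins_cut_at_median(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        edges = fit_bins(times, 2, events=np.ones(4, int))
        np.testing.assert_allclose(edges.cut_points, [2.5])

    def test_censored_times_excluded(self):
        times = np.array([1, 2, 3, 4, 5, 6, 7, 8, 1000.0, 2000.0])
        events = np.array([1] * 8 + [0, 0])
        edges = fit_bins(times, 4, events=events)
        np.testing.assert_allclose(edges.cut_points, [2.75, 4.5, 6.25])

    def test_too_few_uncensored_reports_count(self):
        with pytest.raises(ConfigurationError, match="3"):
            fit_bins(np.array([1.0, 2.0, 3.0, 9.0]), 4,
                     events=np.array([1, 1, 1, 0]))


class TestDiscretize:
    EDGES = BinEdges(np.array([10.0, 20.0, 30.0]))

    def test_time_zero_is_bin_zero(self):
        assert discretize(0.0, self.EDGES) == 0

    def test_cut_point_is_lower_inclusive(self):
        assert discretize(10.0, self.EDGES) == 1
        assert discretize(30.0, self.EDGES) == 3

    def test_beyond_last_cut_is_last_bin(self):
        assert discretize(1e9, self.EDGES) == 3

    def test_negative_time_rejected(self):
        with pytest.raises(ConfigurationError):
            discretize(-1.0, self.EDGES)

    def test_random_times_match_interval_scan_oracle(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(0, 40, 20)
        full = self.EDGES.full_edges
        for t in times:
            expected = next(d for d in range(4)
                            if full[d] <= t < full[d + 1])
            assert discretize(t, self.EDGES) == expected

    def test_quartile_binning_balances_uncensored_counts(self):
        rng = np.random.default_rng(1)
        times = rng.permutation(np.linspace(1, 500, 80))  # distinct times
        edges = fit_bins(times, 4, events=np.ones(80, int))
        bins = discretize(times, edges)
        counts = np.bincount(bins, minlength=4)
        assert all(abs(c - 20) <= 1 for c in counts)


class TestHazardSurvival:
    def test_zero_logits_give_half_hazards(self):
        np.testing.assert_allclose(hazards(np.zeros(4)), 0.5)

    def test_extreme_logit_saturates(self):
        assert hazards(np.array([50.0]))[0] == pytest.approx(1.0)

    def test_hazards_match_formula_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(6)
        np.testing.assert_allclose(hazards(x), 1 / (1 + np.exp(-x)))

    def test_survival_running_product(self):
        s = survival_probs(np.array([0.1, 0.2, 0.3, 0.4]))
        np.testing.assert_allclose(s, [1.0, 0.9, 0.72, 0.504, 0.3024])

    def test_survival_boundaries(self):
        np.testing.assert_allclose(survival_probs(np.zeros(4)), 1.0)
        s = survival_probs(np.ones(4))
        assert s[0] == 1.0 and (s[1:] == 0.0).all()

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=8))
    def test_survival_nonincreasing_bounded(self, haz):
        s = survival_probs(np.array(haz))
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-15).all()
        assert (s >= 0).all() and (s <= 1).all()


class TestNllLoss:
    def test_uncensored_bin0_zero_logits_alpha1_is_log2(self):
        loss = nll_loss(np.zeros(4), bin=0, censor=0,
                        weights=LossWeights(alpha=1.0))
        assert loss == pytest.approx(np.log(2.0), rel=1e-12)

    def test_censored_with_certain_survival_is_zero(self):
        loss = nll_loss(np.full(4, -50.0), bin=2, censor=1)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_alpha_zero_annihilates_uncensored_term(self):
        loss = nll_loss(np.random.default_rng(0).standard_normal(4),
                        bin=1, censor=0, weights=LossWeights(alpha=0.0))
        assert loss == 0.0

    def test_hand_computed_mixed_case(self):
        # uncensored in bin 2: L = -0.5*(log(1-h0)+log(1-h1)+log(h2))
        logits = np.array([0.0, 1.0, -1.0, 2.0])
        h = 1 / (1 + np.exp(-logits))
        expected = -0.5 * (np.log(1 - h[0]) + np.log(1 - h[1]) + np.log(h[2]))
        assert nll_loss(logits, 2, 0) == pytest.approx(expected, rel=1e-12)
        # censored at bin 1: L = -0.5 * sum_{k<=1} log(1-h_k)
        expected_c = -0.5 * (np.log(1 - h[0]) + np.log(1 - h[1]))
        assert nll_loss(logits, 1, 1) == pytest.approx(expected_c, rel=1e-12)

    def test_tensor_path_matches_numpy_and_has_gradient(self):
        rng = np.random.default_rng(3)
        logits = rng.standard_normal(4)
        t = Tensor(logits, requires_grad=True)
        loss_t = nll_loss(t, 1, 0)
        assert loss_t.item() == pytest.approx(nll_loss(logits, 1, 0), rel=1e-10)
        loss_t.backward()
        assert np.abs(t.grad).sum() > 0

    def test_loss_decreases_as_own_bin_hazard_improves(self):
        # uncensored subject in bin 1: raising h_1 toward 1 lowers the loss
        losses = [nll_loss(np.array([-2.0, x, 0.0, 0.0]), 1, 0)
                  for x in np.linspace(-2, 4, 10)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            LossWeights(alpha=1.2)
        with pytest.raises(ConfigurationError):
            LossWeights(alpha=0.4, beta=0.4)


class TestRiskScore:
    def test_zero_hazard_limit(self):
        assert risk_score(np.full(4, -60.0)) == pytest.approx(-4.0)

    def test_certain_hazard_limit(self):
        assert risk_score(np.full(4, 60.0)) == pytest.approx(-1.0)

    def test_matches_survival_oracle(self):
        logits = np.log(np.array([0.1, 0.2, 0.3, 0.4])
                        / (1 - np.array([0.1, 0.2, 0.3, 0.4])))
        assert risk_score(logits) == pytest.approx(-3.124, rel=1e-9)

    def test_monotone_in_each_contributing_hazard(self):
        # risk sums S(0..3); the absorbing last-bin hazard never enters it
        base = np.zeros(4)
        r0 = risk_score(base)
        for d in range(3):
            bumped = base.copy()
            bumped[d] += 1.0
            assert risk_score(bumped) > r0


class TestConcordance:
    def test_perfect_anti_ordering(self):
        times = np.array([1.0, 2, 3, 4, 5])
        risks = -times
        assert concordance_index(risks, times, np.ones(5, int)) == 1.0

    def test_all_tied_risks(self):
        times = np.array([1.0, 2, 3, 4])
        assert concordance_index(np.zeros(4), times, np.ones(4, int)) == 0.5

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(UndefinedMetricError):
            concordance_index([1.0, 2.0], [5.0, 5.0], [0, 0])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_double_loop_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 50)
        times = rng.uniform(0, 100, n).round(1)  # induces occasional ties
        events = rng.integers(0, 2, n)
        risks = rng.standard_normal(n).round(2)
        if not ((events == 1) & (times[:, None] < times[None, :]).any(axis=1)).any():
            return
        assert concordance_index(risks, times, events) == pytest.approx(
            oracle_cindex(risks, times, events), rel=1e-12)

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index as ll_cindex
        rng = np.random.default_rng(42)
        times = rng.uniform(1, 100, 40)
        events = rng.integers(0, 2, 40)
        risks = rng.standard_normal(40)
        ours = concordance_index(risks, times, events)
        # lifelines scores "higher = longer survival", so negate risks
        theirs = ll_cindex(times, -risks, events)
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestTimeDependentAuc:
    def test_perfect_separation_no_censoring(self):
        times = np.arange(1.0, 21.0)
        risks = -times
        aucs, mean_auc = time_dependent_auc(risks, times, np.ones(20, bool),
                                            [5.5, 10.5, 15.5])
        np.testing.assert_allclose(aucs, 1.0)
        assert mean_auc == pytest.approx(1.0)

    def test_random_risks_near_half(self):
        rng = np.random.default_rng(0)
        n = 400
        times = rng.exponential(50, n)
        risks = rng.standard_normal(n)
        _, mean_auc = time_dependent_auc(risks, times, np.ones(n, bool),
                                         np.quantile(times, [0.25, 0.5, 0.75]))
        assert abs(mean_auc - 0.5) < 0.1

    def test_uncensored_single_time_reduces_to_mann_whitney(self):
        rng = np.random.default_rng(1)
        times = np.array([2, 4, 6, 8, 10, 12, 14, 16, 18, 20.0])
        risks = rng.standard_normal(10)
        horizon = 9.0
        cases = risks[times <= horizon]
        controls = risks[times > horizon]
        pairs = [(1.0 if a > b else 0.5 if a == b else 0.0)
                 for a in cases for b in controls]
        expected = float(np.mean(pairs))
        aucs, _ = time_dependent_auc(risks, times, np.ones(10, bool), [horizon])
        assert aucs[0] == pytest.approx(expected, rel=1e-9)

    def test_eval_time_beyond_followup_rejected(self):
        with pytest.raises(UndefinedMetricError):
            time_dependent_auc([1.0, 2.0], [5.0, 10.0], [1, 1], [20.0])


def test_survival_record_validation_and_censor_flag():
    rec = SurvivalRecord("s1", 120.0, 1)
    assert rec.censor == 0
    with pytest.raises(ConfigurationError):
        SurvivalRecord("s2", -5.0, 1)
    with pytest.raises(ConfigurationError):
        SurvivalRecord("s3", 5.0, 2)
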