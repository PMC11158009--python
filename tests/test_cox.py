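"""Cox partial likelihood, memory bank, DeepHit losses, Breslow prediction."""

import numpy as np
import pytest
from scipy.special import logsumexp

from centime import TimeGrid, UntrainableError
from centime.cox import (
    SKIP_BATCH,
    MemoryBank,
    breslow_baseline_hazard,
    cox_partial_loglik,
    cox_partial_loglik_grad,
    cox_predict_time,
    cox_relative_risk,
    coxmb_loglik,
    minibatch_cox_loglik,
    risk_set,
)
from centime.deephit import admissible_pairs, deephit_rank_loss, deephit_total_loss


def naive_partial_loglik(scores, time, status):
    """Oracle: per-subject risk sets built by explicit comparison."""
    terms = []
    for n in np.flatnonzero(np.asarray(status) == 1):
        members = risk_set(time, n)
        terms.append(scores[n] - logsumexp(np.asarray(scores)[members]))
    return float(np.mean(terms))


class TestRelativeRisk:
    def test_two_equal_scores_split_evenly(self):
        assert cox_relative_risk([1.3, 1.3], [0, 1], anchor=0) == pytest.approx(0.5)

    def test_singleton_risk_set(self):
        assert cox_relative_risk([0.7], [0], anchor=0) == pytest.approx(1.0)

    def test_three_member_direct_evaluation(self):
        e = np.exp(1.0)
        expected = e / (e + 1 + 1 / e)
        assert cox_relative_risk([1.0, 0.0, -1.0], [0, 1, 2], anchor=0) == pytest.approx(expected)

    def test_empty_risk_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cox_relative_risk([1.0], [], anchor=0)


class TestPartialLoglik:
    def test_equal_scores_closed_form(self):
        # k uncensored subjects with distinct times: term n is -log |R_n|
        time = np.array([1, 2, 3, 4, 5])
        status = np.ones(5, int)
        scores = np.full(5, 2.0)
        sizes = [5, 4, 3, 2, 1]
        assert cox_partial_loglik(scores, time, status) == pytest.approx(
            np.mean([-np.log(r) for r in sizes])
        )

    def test_lone_subject_scores_zero(self):
        assert cox_partial_loglik([3.0], [4], [1]) == pytest.approx(0.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=20)
        time = rng.integers(1, 15, 20)
        status = rng.integers(0, 2, 20)
        status[0] = 1
        a = cox_partial_loglik(scores, time, status)
        b = cox_partial_loglik(scores + 123.4, time, status)
        assert a == pytest.approx(b, abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_sweep_matches_naive_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        scores = rng.normal(size=n)
        time = rng.integers(1, 8, n)  # many ties
        status = rng.integers(0, 2, n)
        status[rng.integers(0, n)] = 1
        assert cox_partial_loglik(scores, time, status) == pytest.approx(
            naive_partial_loglik(scores, time, status), abs=1e-9
        )

    def test_all_censored_is_untrainable(self):
        with pytest.raises(UntrainableError):
            cox_partial_loglik([1.0, 2.0], [3, 4], [0, 0])

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        n, d = 30, 3
        X = rng.normal(size=(n, d))
        beta = rng.normal(size=d) * 0.3
        time = rng.integers(1, 10, n)
        status = rng.integers(0, 2, n)
        status[:3] = 1
        g = cox_partial_loglik_grad(X @ beta, time, status, X)
        num = np.zeros(d)
        for j in range(d):
            e = np.zeros(d)
            e[j] = 1e-6
            num[j] = (
                cox_partial_loglik(X @ (beta + e), time, status)
                - cox_partial_loglik(X @ (beta - e), time, status)
            ) / 2e-6
        np.testing.assert_allclose(g, num, atol=1e-7)


class TestMinibatch:
    def test_full_batch_equals_partial_loglik(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=15)
        time = rng.integers(1, 10, 15)
        status = rng.integers(0, 2, 15)
        status[0] = 1
        assert minibatch_cox_loglik(scores, time, status) == pytest.approx(
            cox_partial_loglik(scores, time, status)
        )

    def test_all_censored_batch_yields_skip_signal(self):
        out = minibatch_cox_loglik([0.1, 0.2], [3, 5], [0, 0])
        assert out is SKIP_BATCH
        assert out != 0.0 and not out

    def test_single_uncensored_batch_scores_zero(self):
        assert minibatch_cox_loglik([1.7], [4], [1]) == pytest.approx(0.0)


class TestMemoryBank:
    def _bank(self):
        time = np.array([2, 4, 6, 8])
        status = np.array([1, 0, 1, 0])
        bank = MemoryBank(time, status, usage_fraction=1.0)
        bank.update(np.arange(4), np.array([0.5, -0.2, 0.1, 0.9]))
        return bank

    def test_update_read_back_and_isolation(self):
        bank = self._bank()
        bank.update([1], [3.3])
        assert bank.scores[1] == 3.3
        assert bank.scores[0] == 0.5  # untouched
        bank.update([0], [1.1]).update([2], [2.2])
        assert bank.scores[0] == 1.1 and bank.scores[2] == 2.2

    def test_full_sweep_equals_latest_scores(self):
        bank = self._bank()
        latest = np.array([9.0, 8.0, 7.0, 6.0])
        bank.update(np.arange(4), latest)
        np.testing.assert_array_equal(bank.scores, latest)

    def test_unknown_index_rejected(self):
        with pytest.raises(IndexError):
            self._bank().update([7], [1.0])

    def test_invalid_usage_fraction_rejected(self):
        with pytest.raises(ValueError):
            MemoryBank([1], [1], usage_fraction=1.5)


class TestCoxMB:
    def test_k1_full_batch_reduces_to_partial_loglik_exactly(self):
        rng = np.random.default_rng(2)
        n = 20
        time = rng.integers(1, 12, n)
        status = rng.integers(0, 2, n)
        status[0] = 1
        scores = rng.normal(size=n)
        bank = MemoryBank(time, status, usage_fraction=1.0)
        bank.update(np.arange(n), rng.normal(size=n))  # stale, must be ignored
        # identical member sets and weights; agreement at machine precision
        assert coxmb_loglik(np.arange(n), scores, bank) == pytest.approx(
            cox_partial_loglik(scores, time, status), abs=1e-13
        )

    def test_all_censored_batch_is_finite_with_bank(self):
        # 4-subject toy: bank holds two uncensored subjects outside the batch
        time = np.array([2, 4, 6, 8])
        status = np.array([1, 0, 1, 0])
        bank = MemoryBank(time, status, usage_fraction=1.0)
        bank.update(np.arange(4), np.array([0.0, 0.0, 0.0, 0.0]))
        batch = np.array([1, 3])  # both censored
        value = coxmb_loglik(batch, np.array([0.0, 0.0]), bank)
        assert np.isfinite(value)
        # anchors are subjects 0 (risk set all 4) and 2 (risk set {2,3}):
        assert value == pytest.approx(np.mean([-np.log(4), -np.log(2)]))

    def test_k0_reduces_to_minibatch_semantics(self):
        time = np.array([2, 4, 6, 8])
        status = np.array([1, 0, 1, 0])
        bank = MemoryBank(time, status, usage_fraction=0.0)
        assert coxmb_loglik([1, 3], np.zeros(2), bank) is SKIP_BATCH
        mixed = coxmb_loglik([0, 1], np.array([0.3, -0.1]), bank)
        assert mixed == pytest.approx(
            cox_partial_loglik([0.3, -0.1], time[:2], status[:2])
        )

    def test_uninitialised_bank_slots_rejected(self):
        bank = MemoryBank([2, 4, 6], [1, 0, 1], usage_fraction=1.0)
        bank.update([0], [0.5])  # slots 1, 2 stay empty
        with pytest.raises(ValueError, match="uninitialised"):
            coxmb_loglik([0], np.array([0.5]), bank)


class TestDeepHitLosses:
    def test_zero_differences_count_pairs(self):
        time = np.array([1, 2, 3])
        status = np.ones(3, int)
        cdf = np.tile(np.linspace(0.2, 1.0, 5), (3, 1))  # identical subjects
        n_pairs = len(admissible_pairs(time, status))
        assert n_pairs == 3
        assert deephit_rank_loss(cdf, time, status) == pytest.approx(n_pairs)

    def test_single_pair_direct_evaluation(self):
        time = np.array([2, 4])
        status = np.array([1, 0])
        cdf = np.zeros((2, 5))
        cdf[0, 1], cdf[1, 1] = 0.8, 0.3  # d = 0.5 at t_i = 2
        assert deephit_rank_loss(cdf, time, status) == pytest.approx(np.exp(-0.5 / 0.1))

    def test_empty_pair_set_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning, match="no admissible pairs"):
            out = deephit_rank_loss(np.zeros((2, 4)), [3, 3], [1, 1])
        assert out == 0.0

    def test_censored_first_subjects_excluded_from_pairs(self):
        pairs = admissible_pairs([1, 2, 3], [0, 1, 1])
        assert pairs.tolist() == [[1, 2]]

    def test_loss_decreases_as_ordering_improves(self):
        time = np.array([2, 6])
        status = np.array([1, 1])
        losses = []
        for fi in (0.1, 0.4, 0.7, 0.95):
            cdf = np.zeros((2, 8))
            cdf[0, 1], cdf[1, 1] = fi, 0.1
            losses.append(deephit_rank_loss(cdf, time, status))
        assert np.all(np.diff(losses) < 0)

    def test_total_loss_rank_weight_zero_is_classical_ablation(self, random_dist):
        from centime import SurvivalData, dataset_loglik

        n = 6
        dists = [random_dist(10, seed=i) for i in range(n)]
        data = SurvivalData(np.zeros((n, 0)), [1, 0, 1, 0, 1, 0], [2, 3, 5, 1, 7, 4])
        abl = deephit_total_loss(data, dists, rank_weight=0.0)
        assert abl == pytest.approx(
            -dataset_loglik(data, dists, model="classical").total
        )
        full = deephit_total_loss(data, dists, rank_weight=1.0)
        cdf = np.cumsum([d.pmf for d in dists], axis=1)
        assert full == pytest.approx(abl + deephit_rank_loss(cdf, data.time, data.status))

    def test_all_censored_dataset_has_no_rank_term(self, random_dist):
        from centime import SurvivalData, dataset_loglik

        dists = [random_dist(10, seed=i) for i in range(3)]
        data = SurvivalData(np.zeros((3, 0)), [0, 0, 0], [2, 5, 3])
        with pytest.warns(RuntimeWarning):
            total = deephit_total_loss(data, dists, rank_weight=1.0)
        assert total == pytest.approx(-dataset_loglik(data, dists, model="classical").total)


class TestBreslowPrediction:
    def test_extreme_scores_hit_grid_ends(self):
        rng = np.random.default_rng(4)
        n = 40
        scores = rng.normal(size=n) * 0.1
        time = rng.integers(1, 20, n)
        status = rng.integers(0, 2, n)
        status[:5] = 1
        grid = TimeGrid(30)
        earliest_event = time[status == 1].min()
        assert cox_predict_time(scores, time, status, 50.0, grid) == earliest_event
        assert cox_predict_time(scores, time, status, -50.0, grid) == grid.t_max

    def test_one_step_breslow_hand_computation(self):
        # single event at t=5 among 3 subjects with equal scores:
        # H0(t>=5) = 1/3, S(t) = exp(-1/3) > 0.5 for g = 0 -> never crosses
        time = np.array([5, 7, 9])
        status = np.array([1, 0, 0])
        scores = np.zeros(3)
        grid = TimeGrid(10)
        H0 = breslow_baseline_hazard(scores, time, status, grid)
        np.testing.assert_allclose(H0, np.where(grid.times >= 5, 1 / 3, 0.0))
        assert cox_predict_time(scores, time, status, 0.0, grid) == 10
        # a subject risky enough to cross 0.5 at the event time:
        # S(5) = exp(-exp(g)/3) <= 0.5 iff g >= log(3 log 2)
        g = np.log(3 * np.log(2)) + 1e-9
        assert cox_predict_time(scores, time, status, g, grid) == 5

    def test_mean_method_is_restricted_mean(self):
        time = np.array([5, 7, 9])
        status = np.array([1, 0, 0])
        scores = np.zeros(3)
        grid = TimeGrid(10)
        S = np.exp(-breslow_baseline_hazard(scores, time, status, grid))
        expected = 1.0 + S[:-1].sum()
        assert cox_predict_time(scores, time, status, 0.0, grid, method="mean") == pytest.approx(
            expected
        )

    def test_no_events_rejected(self):
        with pytest.raises(UntrainableError):
            breslow_baseline_hazard([0.0], [3], [0], TimeGrid(5))
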