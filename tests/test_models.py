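"""Model/Results layer: fitting, recovery, cross-checks, evaluation."""

import numpy as np
import pytest

from centime import (
    CohortConfig,
    CoxRiskModel,
    DeepHitModel,
    DiscreteTimeEventModel,
    SurvivalData,
    UntrainableError,
    fit_event_model,
    fit_risk_model,
    predict_and_evaluate,
    sample_cohort,
)


def cohort(mechanism, n=600, seed=0, **kw):
    defaults = dict(
        n_subjects=n,
        t_max=60,
        covariate_dim=2,
        intercept=30.0,
        weights=(4.0, -2.0),
        sigma=12.0,
        mechanism=mechanism,
        seed=seed,
    )
    defaults.update(kw)
    return sample_cohort(CohortConfig(**defaults))


class TestEventModelFitting:
    def test_score_matches_finite_differences(self):
        data = cohort("event_conditional", n=80, seed=1)
        for likelihood in ("centime", "classical"):
            for learn_sigma in (False, True):
                model = DiscreteTimeEventModel(
                    data, likelihood=likelihood, t_max=60, learn_sigma=learn_sigma
                )
                p = model.start_params() + 0.3
                g = model.score(p)
                num = np.zeros_like(p)
                for j in range(len(p)):
                    e = np.zeros_like(p)
                    e[j] = 1e-6
                    num[j] = (model.loglike(p + e) - model.loglike(p - e)) / 2e-6
                np.testing.assert_allclose(g, num, atol=1e-6)

    def test_vectorised_loglik_matches_scalar_terms(self):
        from centime import dataset_loglik

        data = cohort("event_conditional", n=40, seed=2)
        model = DiscreteTimeEventModel(data, likelihood="centime", t_max=60)
        p = model.start_params()
        dists = []
        from centime.distributions import DiscreteEventDistribution, gaussian_log_pmf

        mu = p[0] + data.X @ p[1:]
        for row in gaussian_log_pmf(mu, 12.0, model.grid):
            dists.append(DiscreteEventDistribution(model.grid, row))
        expected = dataset_loglik(data, dists, model="centime").mean
        assert model.loglike(p) == pytest.approx(expected, abs=1e-9)

    def test_intercept_recovery_all_uncensored(self):
        mu_true = 30.0
        data = cohort("event_conditional", n=2000, seed=3, weights=(0.0, 0.0), censoring_prob=0.0)
        res = fit_event_model(data, likelihood="centime", t_max=60, sigma=12.0)
        assert abs(res.intercept - mu_true) < 3 * 12.0 / np.sqrt(2000)
        assert res.converged

    def test_objective_trace_monotone_nondecreasing(self):
        data = cohort("event_conditional", n=300, seed=4)
        res = fit_event_model(data, likelihood="centime", t_max=60)
        assert np.all(np.diff(res.trace) > -1e-8)

    def test_learned_sigma_recovers_truth(self):
        data = cohort("event_conditional", n=3000, seed=5, censoring_prob=0.0, sigma=8.0)
        res = fit_event_model(data, likelihood="centime", t_max=60, learn_sigma=True)
        assert res.sigma == pytest.approx(8.0, abs=1.0)

    def test_centime_rejects_censored_at_horizon(self):
        data = SurvivalData(np.zeros((2, 1)), [1, 0], [10, 60])
        with pytest.raises(Exception, match="Tmax"):
            DiscreteTimeEventModel(data, likelihood="centime", t_max=60)

    def test_classical_on_all_censored_warns_degenerate(self):
        data = cohort("fixed_proportion", n=100, seed=6, censored_fraction=1.0)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            DiscreteTimeEventModel(data, likelihood="classical", t_max=60)

    def test_summary_names_parameters(self):
        data = cohort("event_conditional", n=120, seed=7)
        res = fit_event_model(data, likelihood="centime", t_max=60)
        text = res.summary()
        assert "intercept" in text and "x1" in text and "x2" in text


class TestCoxFitting:
    def test_separable_two_group_cohort(self):
        # group A (x ~ 1) always dies before group B (x ~ 0); a small
        # within-group gradient keeps every risk score distinct
        n = 40
        time = np.r_[np.arange(1, 21), np.arange(30, 50)]
        X = (np.r_[np.ones(n // 2), np.zeros(n // 2)] - 0.001 * time)[:, None]
        status = np.ones(n, int)
        data = SurvivalData(X, status, time)
        res = fit_risk_model(data, objective="cox", t_max=60)
        assert res.params[0] > 1.0  # higher x -> higher risk
        assert res.evaluate(data).c_index == 1.0

    def test_sign_recovery_on_classical_cohort(self):
        data = cohort("classical", n=900, seed=8)
        res = fit_risk_model(data, objective="cox", t_max=60)
        # larger mu(x) (longer survival) must map to lower risk
        assert res.params[0] < 0 < res.params[1]
        assert abs(res.params[0]) > abs(res.params[1])

    def test_matches_lifelines_coefficients(self):
        # tie-free subset: Breslow and Efron coincide, so lifelines is an
        # exact independent oracle
        from lifelines import CoxPHFitter

        data = cohort("classical", n=400, seed=9)
        _, first = np.unique(data.time, return_index=True)
        data = data.subset(np.sort(first))
        assert data.n_uncensored > 10
        res = fit_risk_model(data, objective="cox", t_max=60)
        cph = CoxPHFitter()
        cph.fit(data.to_dataframe(), duration_col="time", event_col="status")
        np.testing.assert_allclose(res.params, cph.params_.to_numpy(), atol=5e-4)
        np.testing.assert_allclose(res.bse, cph.standard_errors_.to_numpy(), atol=5e-4)

    def test_minibatch_full_batch_same_optimum(self):
        data = cohort("classical", n=200, seed=10)
        full = fit_risk_model(data, objective="cox", t_max=60)
        mb = fit_risk_model(
            data, objective="cox_minibatch", t_max=60, batch_size=data.n,
            n_epochs=4000, learning_rate=1.0, seed=1,
        )
        np.testing.assert_allclose(mb.params, full.params, atol=1e-3)

    def test_coxmb_tracks_full_batch_optimum(self):
        data = cohort("classical", n=300, seed=11)
        full = fit_risk_model(data, objective="cox", t_max=60)
        mbres = fit_risk_model(
            data, objective="coxmb", t_max=60, batch_size=32, n_epochs=80, seed=2
        )
        np.testing.assert_allclose(mbres.params, full.params, atol=0.05)

    def test_all_censored_untrainable(self):
        data = cohort("fixed_proportion", n=60, seed=12, censored_fraction=1.0)
        with pytest.raises(UntrainableError, match="untrainable"):
            CoxRiskModel(data, objective="cox", t_max=60)


class TestDeepHit:
    def test_likelihood_only_gradient_descent_recovers_ordering(self):
        data = cohort("classical", n=250, seed=13, t_max=24, intercept=12.0, sigma=5.0)
        res = DeepHitModel(data, t_max=24, rank_weight=0.0).fit(maxiter=500)
        rep = res.evaluate(data)
        assert rep.c_index > 0.6

    def test_rank_term_changes_objective(self):
        data = cohort("classical", n=80, seed=14, t_max=20, intercept=10.0, sigma=4.0)
        lik_only = DeepHitModel(data, t_max=20, rank_weight=0.0).fit(maxiter=200)
        with_rank = DeepHitModel(data, t_max=20, rank_weight=1.0).fit(maxiter=200)
        assert lik_only.objective != pytest.approx(with_rank.objective)


class TestEvaluation:
    def test_perfect_model_on_training_times(self):
        time = np.arange(1, 11)
        data = SurvivalData(np.zeros((10, 0)), np.ones(10, int), time)

        class Perfect:
            def evaluate(self, d):
                from centime.metrics import metrics_report

                return metrics_report(d.time.astype(float), d.time, d.status, "time")

        rep = predict_and_evaluate(Perfect(), data)
        assert rep.c_index == 1.0 and rep.mae == 0.0

    def test_evaluation_is_pure(self):
        data = cohort("event_conditional", n=150, seed=15)
        res = fit_event_model(data, likelihood="centime", t_max=60)
        a, b = res.evaluate(data), res.evaluate(data)
        assert a == b

    def test_point_estimate_flag_changes_predictions(self):
        data = cohort("event_conditional", n=100, seed=16)
        res = fit_event_model(data, likelihood="centime", t_max=60)
        mean_t = res.predict_time(data.X, method="mean")
        mode_t = res.predict_time(data.X, method="mode")
        assert mean_t.shape == mode_t.shape == (100,)
        assert np.all(np.abs(mean_t - mode_t) < 2.0)  # smooth model: close but not equal
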