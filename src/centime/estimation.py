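"""High-level fitting and the censoring-sweep experiment.

These functions are thin conveniences over the Model/Results classes in
:mod:`centime.models`; the sweep re-creates, on synthetic cohorts, the study
of estimator behaviour as the fraction of available uncensored records
grows from 0% (purely censored training data) to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalData
from .exceptions import UndefinedMetricError, UntrainableError
from .metrics import MetricsReport
from .models import CoxRiskModel, CoxResults, DeepHitModel, DiscreteTimeEventModel
from .simulate import CohortConfig, sample_cohort

__all__ = [
    "fit_event_model",
    "fit_risk_model",
    "predict_and_evaluate",
    "SweepConfig",
    "censoring_sweep_experiment",
    "parameter_recovery_experiment",
    "consistency_ladder",
]


def fit_event_model(
    data: SurvivalData,
    likelihood: str = "centime",
    t_max: int = 156,
    sigma: float = 12.0,
    learn_sigma: bool = False,
    **fit_kwargs,
):
    """Fit a discretised-Gaussian event model by maximum likelihood."""
    return DiscreteTimeEventModel(
        data, likelihood=likelihood, t_max=t_max, sigma=sigma, learn_sigma=learn_sigma
    ).fit(**fit_kwargs)


def fit_risk_model(data: SurvivalData, objective: str = "cox", **kwargs) -> CoxResults:
    """Fit a linear Cox risk model under the chosen partial-likelihood objective."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("start_params", "maxiter", "tol") if k in kwargs}
    return CoxRiskModel(data, objective=objective, **kwargs).fit(**fit_kwargs)


def predict_and_evaluate(results, data: SurvivalData) -> MetricsReport:
    """Metrics for any fitted Results object on a cohort.

    Event and DeepHit models are scored on the time scale via their
    distribution means; Cox models on the risk scale (C-index) with
    Breslow-median times for MAE/RAE. Evaluation is a pure function of the
    fitted parameters and the data.
    """
    return results.evaluate(data)


def parameter_recovery_experiment(
    n_subjects: int,
    n_replicates: int = 20,
    seed: int = 0,
    likelihood: str = "centime",
    t_max: int = 60,
    covariate_dim: int = 2,
    intercept: float = 30.0,
    weights: tuple[float, ...] = (4.0, -2.0),
    sigma: float = 12.0,
    censored_fraction: float = 1.0,
) -> pd.DataFrame:
    """Seeded replicates of MLE fitting on fixed-proportion cohorts.

    Generates ``n_replicates`` cohorts with an exact censored fraction
    (default 1.0: purely censored data, the regime where the
    event-conditional likelihood remains consistent while the classical one
    does not), fits the chosen likelihood to each, and returns one row per
    replicate with the estimated intercept and weights beside the truth.
    """
    import warnings as _warnings

    root = np.random.SeedSequence(seed)
    rows = []
    for rep, ss in enumerate(root.spawn(n_replicates)):
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        cfg = CohortConfig(
            n_subjects=n_subjects,
            t_max=t_max,
            covariate_dim=covariate_dim,
            intercept=intercept,
            weights=weights,
            sigma=sigma,
            mechanism="fixed_proportion",
            censored_fraction=censored_fraction,
            seed=rep_seed,
        )
        data = sample_cohort(cfg)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            res = fit_event_model(data, likelihood=likelihood, t_max=t_max, sigma=sigma)
        row = {
            "replicate": rep,
            "seed": rep_seed,
            "n": n_subjects,
            "likelihood": likelihood,
            "converged": res.converged,
            "intercept_hat": res.intercept,
            "intercept_true": intercept,
            "intercept_error": res.intercept - intercept,
        }
        for j, (w_hat, w_true) in enumerate(zip(res.weights, weights), start=1):
            row[f"w{j}_hat"] = w_hat
            row[f"w{j}_true"] = w_true
            row[f"w{j}_error"] = w_hat - w_true
        rows.append(row)
    return pd.DataFrame(rows)


def consistency_ladder(
    sample_sizes: tuple[int, ...] = (250, 1000, 4000),
    n_replicates: int = 20,
    seed: int = 0,
    likelihood: str = "centime",
    t_max: int = 60,
    covariate_dim: int = 2,
    intercept: float = 30.0,
    weights: tuple[float, ...] = (4.0, -2.0),
    sigma: float = 12.0,
    censored_fraction: float = 1.0,
) -> pd.DataFrame:
    """Estimation error versus sample size on nested censored cohorts.

    Per replicate one cohort of max(sample_sizes) subjects is drawn and the
    model is fitted to its first n rows for each ladder step, so the errors
    at successive n are positively correlated within a replicate — the
    common-random-number design that gives a monotonicity check on median
    bias far more power than independent cohorts per n would.
    """
    import warnings as _warnings

    n_max = max(sample_sizes)
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, ss in enumerate(root.spawn(n_replicates)):
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        cfg = CohortConfig(
            n_subjects=n_max,
            t_max=t_max,
            covariate_dim=covariate_dim,
            intercept=intercept,
            weights=weights,
            sigma=sigma,
            mechanism="fixed_proportion",
            censored_fraction=censored_fraction,
            seed=rep_seed,
        )
        full = sample_cohort(cfg)
        for n in sample_sizes:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                res = fit_event_model(
                    full.subset(np.arange(n)), likelihood=likelihood, t_max=t_max, sigma=sigma
                )
            rows.append(
                {
                    "replicate": rep,
                    "n": n,
                    "likelihood": likelihood,
                    "converged": res.converged,
                    "intercept_error": res.intercept - intercept,
                    "max_weight_error": float(np.max(np.abs(res.weights - np.asarray(weights))))
                    if len(weights)
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepConfig:
    """Design of the uncensored-fraction sweep.

    A full training cohort is generated by the event-conditional mechanism;
    for each fraction f, round(f * n_uncensored) uncensored records are
    subsampled while every censored record is kept, each estimator is fitted
    on the reduced cohort, and metrics are computed on a held-out
    all-uncensored test set.
    """

    n_train: int = 800
    n_test: int = 300
    t_max: int = 60
    covariate_dim: int = 2
    intercept: float = 30.0
    weights: tuple[float, ...] = (4.0, -2.0)
    sigma: float = 12.0
    censoring_prob: float = 0.65
    fractions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    methods: tuple[str, ...] = ("centime", "classical", "cox")
    n_replicates: int = 10
    seed: int = 0

    def cohort_config(self, n: int, mechanism: str, seed: int, censoring_prob=None) -> CohortConfig:
        return CohortConfig(
            n_subjects=n,
            t_max=self.t_max,
            covariate_dim=self.covariate_dim,
            intercept=self.intercept,
            weights=self.weights,
            sigma=self.sigma,
            mechanism=mechanism,
            censoring_prob=self.censoring_prob if censoring_prob is None else censoring_prob,
            seed=seed,
        )


def _fit_and_evaluate(method: str, train: SurvivalData, test: SurvivalData, config: SweepConfig):
    if method in ("centime", "classical"):
        res = fit_event_model(
            train, likelihood=method, t_max=config.t_max, sigma=config.sigma
        )
    elif method == "cox":
        res = fit_risk_model(train, objective="cox", t_max=config.t_max)
    elif method in ("deephit", "deephit-lik"):
        res = DeepHitModel(
            train, t_max=config.t_max, rank_weight=1.0 if method == "deephit" else 0.0
        ).fit()
    else:
        raise ValueError(f"unknown method {method!r}")
    return res.evaluate(test)


def censoring_sweep_experiment(config: SweepConfig) -> pd.DataFrame:
    """Estimator performance as uncensored data is gradually admitted.

    Returns a tidy table with one row per (fraction, method, metric):
    columns fraction, method, metric, mean, sd, median, n_replicates,
    status. Cox rows at fractions leaving no uncensored record carry
    status='untrainable' with NaN metrics (the partial likelihood is
    undefined there); event-conditional rows remain finite.
    """
    rows = []
    root = np.random.SeedSequence(config.seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(config.n_replicates)]
    for rep, rep_seed in enumerate(rep_seeds):
        train_full = sample_cohort(
            config.cohort_config(config.n_train, "event_conditional", rep_seed)
        )
        test = sample_cohort(
            config.cohort_config(config.n_test, "event_conditional", rep_seed + 1, censoring_prob=0.0)
        )
        rng = np.random.default_rng(rep_seed + 2)
        uncens = train_full.uncensored_index
        cens = train_full.censored_index
        uncens_shuffled = rng.permutation(uncens)
        for frac in config.fractions:
            keep_u = uncens_shuffled[: int(round(frac * len(uncens)))]
            train = train_full.subset(np.sort(np.concatenate([cens, keep_u])))
            for method in config.methods:
                try:
                    report = _fit_and_evaluate(method, train, test, config)
                    status = "ok"
                    values = {"c_index": report.c_index, "mae": report.mae, "rae": report.rae}
                except (UntrainableError, UndefinedMetricError):
                    status = "untrainable"
                    values = {"c_index": np.nan, "mae": np.nan, "rae": np.nan}
                for metric, value in values.items():
                    rows.append(
                        {
                            "replicate": rep,
                            "fraction": frac,
                            "method": method,
                            "metric": metric,
                            "value": value,
                            "status": status,
                        }
                    )
    raw = pd.DataFrame(rows)
    agg = (
        raw.groupby(["fraction", "method", "metric"], as_index=False)
        .agg(
            mean=("value", "mean"),
            sd=("value", "std"),
            median=("value", "median"),
            n_replicates=("value", "size"),
            status=("status", lambda s: "untrainable" if (s == "untrainable").all() else "ok"),
        )
        .sort_values(["fraction", "method", "metric"], ignore_index=True)
    )
    agg.attrs["replicates"] = raw
    return agg
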