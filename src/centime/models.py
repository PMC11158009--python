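"""Model/Results classes for maximum-likelihood survival fitting.

Three model families, all linear in the covariates:

* :class:`DiscreteTimeEventModel` — a discretised-Gaussian event-time model
  mu(x) = intercept + w.x with sigma fixed (default, 12 months) or learned,
  fitted by maximising either the event-conditional (CenTime) or the
  classical censored likelihood.
* :class:`CoxRiskModel` — linear risk scores g(x) = beta.x fitted by the Cox
  partial likelihood, its minibatch variant, or the memory-bank (CoxMB)
  objective.
* :class:`DeepHitModel` — per-time logits l_t(x) = a_t + b_t.x softmaxed
  into a death distribution, fitted by the classical likelihood plus an
  optional ranking penalty.

Each ``fit()`` returns a Results object carrying the estimates, standard
errors from the observed information where available, the objective trace,
and ``summary()``. Full-batch fits use L-BFGS (a deterministic
quasi-second-order ascent whose accepted iterates never decrease the
objective); minibatch fits use plain seeded gradient ascent. Convergence is
declared when the objective changes by less than ``tol`` (default 1e-7) for
five successive accepted iterates, up to ``maxiter`` (default 2000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import cox as _cox
from .data import SurvivalData
from .distributions import DiscreteEventDistribution, TimeGrid, gaussian_log_pmf
from .exceptions import UntrainableError
from .metrics import MetricsReport, metrics_report

__all__ = [
    "DiscreteTimeEventModel",
    "EventModelResults",
    "CoxRiskModel",
    "CoxResults",
    "DeepHitModel",
    "DeepHitResults",
]

CONVERGENCE_TOL = 1e-7
CONVERGENCE_STREAK = 5
MAXITER = 2000


def _design(data: SurvivalData) -> np.ndarray:
    return np.column_stack([np.ones(data.n), data.X])


def _trace_converged(trace: np.ndarray, tol: float, streak: int) -> bool:
    if len(trace) < streak + 1:
        return False
    return bool(np.all(np.abs(np.diff(trace[-(streak + 1):])) < tol))


def _numerical_hessian(grad_fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    k = len(x)
    H = np.zeros((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = eps * max(1.0, abs(x[j]))
        H[:, j] = (grad_fn(x + step) - grad_fn(x - step)) / (2 * step[j])
    return 0.5 * (H + H.T)


def _se_from_hessian(neg_hess: np.ndarray) -> np.ndarray:
    """Standard errors from the observed information; NaN if not invertible."""
    try:
        cov = np.linalg.inv(neg_hess)
        d = np.diag(cov)
        return np.where(d > 0, np.sqrt(np.maximum(d, 0)), np.nan)
    except np.linalg.LinAlgError:
        return np.full(neg_hess.shape[0], np.nan)


def _summary_frame(names, params, bse) -> pd.DataFrame:
    frame = pd.DataFrame({"coef": params, "std err": bse}, index=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        frame["z"] = frame["coef"] / frame["std err"]
    return frame


# ---------------------------------------------------------------------------
# Discretised-Gaussian event models (CenTime / classical likelihoods)
# ---------------------------------------------------------------------------


class DiscreteTimeEventModel:
    """Covariate-conditioned discretised-Gaussian event-time model.

    Parameters
    ----------
    data : training cohort.
    likelihood : 'centime' (event-conditional censoring) or 'classical'
        (independent uniform censoring).
    t_max : horizon of the discrete grid, months.
    sigma : event-time scale, months; fixed unless ``learn_sigma``.
    learn_sigma : estimate sigma by ML through an unconstrained log
        reparameterisation (sigma stays positive by construction).
    """

    def __init__(
        self,
        data: SurvivalData,
        likelihood: str = "centime",
        t_max: int = 156,
        sigma: float = 12.0,
        learn_sigma: bool = False,
    ) -> None:
        if likelihood not in ("centime", "classical"):
            raise ValueError(f"unknown likelihood {likelihood!r}")
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        data.validate_for_grid(t_max, likelihood=likelihood)
        if likelihood == "classical" and data.n_uncensored == 0:
            warnings.warn(
                "classical likelihood on an all-censored cohort is degenerate: "
                "the objective pushes all event mass beyond the censoring times",
                RuntimeWarning,
                stacklevel=2,
            )
        self.data = data
        self.likelihood = likelihood
        self.grid = TimeGrid(t_max)
        self.sigma = float(sigma)
        self.learn_sigma = bool(learn_sigma)
        self._D = _design(data)
        self._uncens = data.status == 1
        # log weights of the censored sum: -log(t-1) (CenTime) or 0 (classical)
        logw = np.zeros(t_max)
        if likelihood == "centime":
            logw[0] = -np.inf
            logw[1:] = -np.log(self.grid.times[1:] - 1.0)
        self._cens_logw = logw
        # per-subject mask of admissible death times for censored records: t > c
        self._cens_mask = self.grid.times[None, :] > data.time[:, None]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DiscreteTimeEventModel":
        return cls(SurvivalData.from_dataframe(df), **kwargs)

    @property
    def param_names(self) -> list[str]:
        names = ["intercept", *self.data.covariate_names]
        if self.learn_sigma:
            names.append("log_sigma")
        return names

    def start_params(self) -> np.ndarray:
        """Deterministic initialisation: intercept at the grid midpoint, weights zero."""
        p = np.zeros(self._D.shape[1] + (1 if self.learn_sigma else 0))
        p[0] = (self.grid.t_max + 1) / 2.0
        if self.learn_sigma:
            p[-1] = np.log(self.sigma)
        return p

    def _split(self, params: np.ndarray) -> tuple[np.ndarray, float]:
        if self.learn_sigma:
            return params[:-1], float(np.exp(params[-1]))
        return params, self.sigma

    def loglike(self, params: np.ndarray) -> float:
        """Mean per-observation censored-data log-likelihood."""
        return self._loglike_and_score(np.asarray(params, float))[0]

    def score(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient of :meth:`loglike`."""
        return self._loglike_and_score(np.asarray(params, float))[1]

    def _loglike_and_score(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        beta, sigma = self._split(params)
        data, grid = self.data, self.grid
        t = grid.times.astype(float)
        mu = self._D @ beta
        f = -((t[None, :] - mu[:, None]) ** 2) / (2 * sigma**2)
        logp = f - logsumexp(f, axis=1, keepdims=True)
        p = np.exp(logp)
        Et = p @ t
        dev2 = (t[None, :] - mu[:, None]) ** 2
        E_dev2 = np.sum(p * dev2, axis=1)

        ll = np.empty(data.n)
        dmu = np.empty(data.n)  # d loglik_i / d mu_i
        dlsig = np.empty(data.n)  # d loglik_i / d log sigma

        u = self._uncens
        if np.any(u):
            ti = data.time[u]
            ll[u] = logp[u, ti - 1]
            dmu[u] = (ti - Et[u]) / sigma**2
            dlsig[u] = ((ti - mu[u]) ** 2 - E_dev2[u]) / sigma**2
        c = ~u
        if np.any(c):
            W = np.where(self._cens_mask[c], logp[c] + self._cens_logw[None, :], -np.inf)
            s = logsumexp(W, axis=1)
            ll[c] = s
            with np.errstate(invalid="ignore"):
                q = np.exp(W - s[:, None])
            q = np.nan_to_num(q)
            dmu[c] = (q @ t - Et[c]) / sigma**2
            dlsig[c] = (np.sum(q * dev2[c], axis=1) - E_dev2[c]) / sigma**2

        grad_beta = self._D.T @ dmu / data.n
        if self.learn_sigma:
            grad = np.concatenate([grad_beta, [np.sum(dlsig) / data.n]])
        else:
            grad = grad_beta
        return float(np.mean(ll)), grad

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = MAXITER,
        tol: float = CONVERGENCE_TOL,
    ) -> "EventModelResults":
        """Maximise the mean log-likelihood by L-BFGS from the stated start."""
        x0 = np.asarray(start_params, float) if start_params is not None else self.start_params()
        f0, _ = self._loglike_and_score(x0)
        if not np.isfinite(f0):
            raise UntrainableError(
                f"objective is {f0} at the initialisation {x0}; "
                "check censored times against Tmax"
            )
        trace = [f0]

        def neg(params):
            ll, g = self._loglike_and_score(params)
            return -ll, -g

        res = minimize(
            neg,
            x0,
            jac=True,
            method="L-BFGS-B",
            callback=lambda xk: trace.append(self.loglike(xk)),
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        trace_arr = np.asarray(trace)
        converged = bool(res.success) or _trace_converged(trace_arr, tol, CONVERGENCE_STREAK)
        neg_hess = -_numerical_hessian(self.score, res.x) * self.data.n
        bse = _se_from_hessian(neg_hess)
        return EventModelResults(
            model=self,
            params=res.x,
            llf=float(-res.fun) * self.data.n,
            llf_per_obs=float(-res.fun),
            bse=bse,
            trace=trace_arr,
            converged=converged,
            n_iter=int(res.nit),
        )


@dataclass
class EventModelResults:
    """Fitted discretised-Gaussian event model."""

    model: DiscreteTimeEventModel
    params: np.ndarray
    llf: float
    llf_per_obs: float
    bse: np.ndarray
    trace: np.ndarray = field(repr=False)
    converged: bool = True
    n_iter: int = 0

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def weights(self) -> np.ndarray:
        end = -1 if self.model.learn_sigma else len(self.params)
        return np.asarray(self.params[1:end])

    @property
    def sigma(self) -> float:
        return float(np.exp(self.params[-1])) if self.model.learn_sigma else self.model.sigma

    def predict_mu(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.intercept + X @ self.weights

    def predict_log_pmf(self, X: np.ndarray) -> np.ndarray:
        """Matrix of per-subject log-pmfs over the grid."""
        return gaussian_log_pmf(self.predict_mu(X), self.sigma, self.model.grid)

    def predict_distributions(self, X: np.ndarray) -> list[DiscreteEventDistribution]:
        lp = self.predict_log_pmf(X)
        return [DiscreteEventDistribution(self.model.grid, row) for row in lp]

    def predict_time(self, X: np.ndarray, method: str = "mean") -> np.ndarray:
        """Point death-time predictions (distribution mean by default)."""
        lp = self.predict_log_pmf(X)
        p = np.exp(lp)
        if method == "mean":
            return p @ self.model.grid.times
        if method == "mode":
            return self.model.grid.times[np.argmax(p, axis=1)].astype(float)
        raise ValueError(f"unknown point-estimate method {method!r}")

    def evaluate(self, data: SurvivalData, point: str = "mean") -> MetricsReport:
        """C-index (time direction), MAE and RAE on a cohort."""
        pred = self.predict_time(data.X, method=point)
        return metrics_report(pred, data.time, data.status, direction="time")

    def summary(self) -> str:
        head = (
            f"Discrete-time event model ({self.model.likelihood} likelihood)\n"
            f"n={self.model.data.n} (uncensored {self.model.data.n_uncensored}), "
            f"Tmax={self.model.grid.t_max}, sigma={self.sigma:.3f}"
            f"{' (learned)' if self.model.learn_sigma else ' (fixed)'}\n"
            f"log-likelihood {self.llf:.3f} (per obs {self.llf_per_obs:.6f}), "
            f"converged={self.converged}, iterations={self.n_iter}\n"
        )
        return head + _summary_frame(self.model.param_names, self.params, self.bse).to_string()


# ---------------------------------------------------------------------------
# Cox-family risk models
# ---------------------------------------------------------------------------


class CoxRiskModel:
    """Linear Cox risk model g(x) = beta.x under a chosen training objective.

    ``objective`` is one of 'cox' (full-batch partial likelihood),
    'cox_minibatch' (within-batch partial likelihood, all-censored batches
    skipped) or 'coxmb' (memory-bank risk sets at usage fraction K).
    """

    def __init__(
        self,
        data: SurvivalData,
        objective: str = "cox",
        t_max: int = 156,
        batch_size: int = 64,
        usage_fraction: float = 1.0,
        learning_rate: float = 0.5,
        n_epochs: int = 200,
        seed: int = 0,
    ) -> None:
        if objective not in ("cox", "cox_minibatch", "coxmb"):
            raise ValueError(f"unknown objective {objective!r}")
        if data.n_uncensored == 0:
            raise UntrainableError(
                "Cox objectives are defined over uncensored subjects only; "
                "this cohort has none and the model is untrainable"
            )
        data.validate_for_grid(t_max, likelihood="classical")
        self.data = data
        self.objective = objective
        self.grid = TimeGrid(t_max)
        self.batch_size = int(batch_size)
        self.usage_fraction = float(usage_fraction)
        self.learning_rate = float(learning_rate)
        self.n_epochs = int(n_epochs)
        self.seed = int(seed)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CoxRiskModel":
        return cls(SurvivalData.from_dataframe(df), **kwargs)

    def loglike(self, beta: np.ndarray) -> float:
        scores = self.data.X @ np.asarray(beta, float)
        return _cox.cox_partial_loglik(scores, self.data.time, self.data.status)

    def score(self, beta: np.ndarray) -> np.ndarray:
        s = self.data.X @ np.asarray(beta, float)
        return _cox.cox_partial_loglik_grad(s, self.data.time, self.data.status, self.data.X)

    def _fit_full_batch(self, x0, maxiter, tol) -> tuple[np.ndarray, np.ndarray, bool, int]:
        trace = [self.loglike(x0)]
        res = minimize(
            lambda b: (-self.loglike(b), -self.score(b)),
            x0,
            jac=True,
            method="L-BFGS-B",
            callback=lambda xk: trace.append(self.loglike(xk)),
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        trace_arr = np.asarray(trace)
        converged = bool(res.success) or _trace_converged(trace_arr, tol, CONVERGENCE_STREAK)
        return res.x, trace_arr, converged, int(res.nit)

    def _fit_minibatch(self, x0, tol) -> tuple[np.ndarray, np.ndarray, bool, int]:
        """Seeded gradient ascent over shuffled minibatches.

        'coxmb' keeps a memory bank of the latest scores; 'cox_minibatch'
        skips all-censored batches per the skip-signal contract.
        """
        rng = np.random.default_rng(self.seed)
        data = self.data
        beta = x0.copy()
        bank = _cox.MemoryBank(data.time, data.status, self.usage_fraction)
        if self.objective == "coxmb":
            bank.update(np.arange(data.n), data.X @ beta)
        trace = []
        for epoch in range(self.n_epochs):
            order = rng.permutation(data.n)
            lr = self.learning_rate / (1.0 + 0.05 * epoch)
            for start in range(0, data.n, self.batch_size):
                idx = order[start : start + self.batch_size]
                sub = data.subset(idx)
                scores = sub.X @ beta
                if self.objective == "coxmb":
                    value, dscores = _cox.coxmb_loglik(idx, scores, bank, rng=rng, return_grad=True)
                    bank.update(idx, scores)
                    if value is _cox.SKIP_BATCH:
                        continue
                    g = sub.X.T @ dscores
                else:
                    value = _cox.minibatch_cox_loglik(scores, sub.time, sub.status)
                    if value is _cox.SKIP_BATCH:
                        continue
                    g = _cox.cox_partial_loglik_grad(scores, sub.time, sub.status, sub.X)
                beta = beta + lr * g
            trace.append(self.loglike(beta))
            if _trace_converged(np.asarray(trace), tol, CONVERGENCE_STREAK):
                return beta, np.asarray(trace), True, epoch + 1
        return beta, np.asarray(trace), False, self.n_epochs

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = MAXITER,
        tol: float = CONVERGENCE_TOL,
    ) -> "CoxResults":
        d = self.data.n_covariates
        x0 = np.asarray(start_params, float) if start_params is not None else np.zeros(d)
        if self.objective == "cox":
            beta, trace, converged, n_iter = self._fit_full_batch(x0, maxiter, tol)
            neg_hess = -_numerical_hessian(self.score, beta) * self.data.n_uncensored
            bse = _se_from_hessian(neg_hess)
        else:
            beta, trace, converged, n_iter = self._fit_minibatch(x0, tol)
            bse = np.full(d, np.nan)
        return CoxResults(
            model=self,
            params=beta,
            llf=self.loglike(beta) if d else 0.0,
            bse=bse,
            trace=trace,
            converged=converged,
            n_iter=n_iter,
        )


@dataclass
class CoxResults:
    """Fitted linear Cox risk model."""

    model: CoxRiskModel
    params: np.ndarray
    llf: float
    bse: np.ndarray
    trace: np.ndarray = field(repr=False)
    converged: bool = True
    n_iter: int = 0

    def predict_risk(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, float)) @ self.params

    def predict_time(self, X: np.ndarray, method: str = "median") -> np.ndarray:
        """Breslow-baseline survival-curve crossing times (months)."""
        train_scores = self.model.data.X @ self.params
        new_scores = self.predict_risk(X)
        return np.array(
            [
                _cox.cox_predict_time(
                    train_scores,
                    self.model.data.time,
                    self.model.data.status,
                    s,
                    self.model.grid,
                    method=method,
                )
                for s in new_scores
            ]
        )

    def evaluate(self, data: SurvivalData) -> MetricsReport:
        """C-index from risk scores; MAE/RAE from Breslow-median times."""
        from .metrics import concordance_index, mae, rae

        risk = self.predict_risk(data.X)
        times = self.predict_time(data.X)
        comparable = (data.status[:, None] == 1) & (data.time[:, None] < data.time[None, :])
        return MetricsReport(
            c_index=concordance_index(risk, data.time, data.status, direction="risk"),
            mae=mae(times, data.time, data.status),
            rae=rae(times, data.time, data.status),
            n_uncensored_evaluated=data.n_uncensored,
            n_pairs_evaluated=int(np.sum(comparable)),
        )

    def summary(self) -> str:
        head = (
            f"Cox risk model (objective={self.model.objective})\n"
            f"n={self.model.data.n} (uncensored {self.model.data.n_uncensored})\n"
            f"mean partial log-likelihood {self.llf:.6f}, "
            f"converged={self.converged}, iterations={self.n_iter}\n"
        )
        return head + _summary_frame(
            list(self.model.data.covariate_names), self.params, self.bse
        ).to_string()


# ---------------------------------------------------------------------------
# DeepHit-style softmax classifier over the grid
# ---------------------------------------------------------------------------


class DeepHitModel:
    """Linear softmax death-time classifier with an optional ranking penalty.

    Each subject's distribution is softmax(a + B x) over the Tmax grid
    times. The loss is the negated classical likelihood objective plus
    ``rank_weight`` times the pairwise rank term; ``rank_weight=0`` is the
    likelihood-only ablation.
    """

    def __init__(
        self,
        data: SurvivalData,
        t_max: int = 156,
        rank_weight: float = 1.0,
        rank_scale: float = 0.1,
    ) -> None:
        data.validate_for_grid(t_max, likelihood="classical")
        self.data = data
        self.grid = TimeGrid(t_max)
        self.rank_weight = float(rank_weight)
        self.rank_scale = float(rank_scale)
        self._D = _design(data)
        self._cens_mask = self.grid.times[None, :] > data.time[:, None]
        from .deephit import admissible_pairs

        self._pairs = admissible_pairs(data.time, data.status)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DeepHitModel":
        return cls(SurvivalData.from_dataframe(df), **kwargs)

    def _unpack(self, params: np.ndarray) -> np.ndarray:
        return params.reshape(self._D.shape[1], self.grid.t_max)

    def start_params(self) -> np.ndarray:
        return np.zeros(self._D.shape[1] * self.grid.t_max)

    def _loss_and_grad(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        W = self._unpack(np.asarray(params, float))
        data, T = self.data, self.grid.t_max
        logits = self._D @ W
        logp = logits - logsumexp(logits, axis=1, keepdims=True)
        p = np.exp(logp)
        dlogits = np.zeros_like(logits)  # d(loss)/d(logits)
        loss = 0.0

        u = data.status == 1
        if np.any(u):
            ti = data.time[u] - 1
            loss -= float(np.sum(logp[u, ti]))
            onehot = np.zeros((int(np.sum(u)), T))
            onehot[np.arange(len(ti)), ti] = 1.0
            dlogits[u] -= onehot - p[u]
        c = ~u
        if np.any(c):
            Wc = np.where(self._cens_mask[c], logp[c], -np.inf)
            s = logsumexp(Wc, axis=1)
            loss -= float(np.sum(s))
            with np.errstate(invalid="ignore"):
                q = np.nan_to_num(np.exp(Wc - s[:, None]))
            dlogits[c] -= q - p[c]

        if self.rank_weight and len(self._pairs):
            sscale = self.rank_scale
            F = np.cumsum(p, axis=1)
            i_idx, j_idx = self._pairs[:, 0], self._pairs[:, 1]
            ti = data.time[i_idx] - 1
            eta = np.exp(-(F[i_idx, ti] - F[j_idx, ti]) / sscale)
            loss += self.rank_weight * float(np.sum(eta))
            # dL/dF(subject, t_i) accumulated per (subject, grid point)
            coeff = np.zeros_like(F)
            np.add.at(coeff, (i_idx, ti), -self.rank_weight * eta / sscale)
            np.add.at(coeff, (j_idx, ti), self.rank_weight * eta / sscale)
            # chain through F = cumsum(p): dL/dp[:,k] = sum_{t>=k} coeff[:,t]
            dF = np.cumsum(coeff[:, ::-1], axis=1)[:, ::-1]
            # softmax jacobian: dL/dlogits = p * (dF - sum_t p_t dF_t)
            dlogits += p * (dF - np.sum(p * dF, axis=1, keepdims=True))

        grad = (self._D.T @ dlogits).ravel() / data.n
        return loss / data.n, grad

    def fit(self, maxiter: int = MAXITER, tol: float = CONVERGENCE_TOL) -> "DeepHitResults":
        x0 = self.start_params()
        trace = [-self._loss_and_grad(x0)[0]]
        res = minimize(
            self._loss_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            callback=lambda xk: trace.append(-self._loss_and_grad(xk)[0]),
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        trace_arr = np.asarray(trace)
        converged = bool(res.success) or _trace_converged(trace_arr, tol, CONVERGENCE_STREAK)
        return DeepHitResults(
            model=self,
            params=res.x,
            objective=float(-res.fun),
            trace=trace_arr,
            converged=converged,
            n_iter=int(res.nit),
        )


@dataclass
class DeepHitResults:
    """Fitted softmax death-time classifier."""

    model: DeepHitModel
    params: np.ndarray
    objective: float
    trace: np.ndarray = field(repr=False)
    converged: bool = True
    n_iter: int = 0

    def predict_log_pmf(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        D = np.column_stack([np.ones(len(X)), X])
        logits = D @ self.model._unpack(self.params)
        return logits - logsumexp(logits, axis=1, keepdims=True)

    def predict_time(self, X: np.ndarray, method: str = "mean") -> np.ndarray:
        p = np.exp(self.predict_log_pmf(X))
        if method == "mean":
            return p @ self.model.grid.times
        if method == "mode":
            return self.model.grid.times[np.argmax(p, axis=1)].astype(float)
        raise ValueError(f"unknown point-estimate method {method!r}")

    def evaluate(self, data: SurvivalData) -> MetricsReport:
        pred = self.predict_time(data.X)
        return metrics_report(pred, data.time, data.status, direction="time")

    def summary(self) -> str:
        return (
            f"DeepHit-style model (rank_weight={self.model.rank_weight}, "
            f"s={self.model.rank_scale})\n"
            f"n={self.model.data.n}, Tmax={self.model.grid.t_max}, "
            f"objective (mean neg. loss) {-self.objective:.6f}, "
            f"converged={self.converged}, iterations={self.n_iter}"
        )
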