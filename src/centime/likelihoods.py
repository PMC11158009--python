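"""Censored-data likelihoods for discrete event-time distributions.

Two generative accounts of right censoring are implemented.

Event-conditional (CenTime): the death time t is drawn from p(D=t|x) first
and the censoring time c is then drawn uniformly on {1..t-1}, giving the
censored-time marginal

    p(C=c|x) = sum_{t=c+1}^{Tmax} p(D=t|x) / (t-1).

Each term of the resulting mixture log-likelihood is a consistent objective
for the event-model parameters, so the model remains estimable from purely
censored data.

Classical: t and c are drawn independently (c uniform on {1..Tmax}) and the
smaller determines the record:

    p(delta=0, C=c|x) = (1/Tmax) sum_{t=c+1}^{Tmax} p(D=t|x),
    p(delta=1, D=t|x) = (Tmax - t + 1)/Tmax * p(D=t|x).

The training objective for the classical model conventionally omits the
additive constants, leaving log sum_{t>c} p(D=t|x) for censored records and
log p(D=t|x) for uncensored ones; the fully normalised probability forms are
retained for the normalisation identities. The only difference between the
two censored objectives is the 1/(t-1) weight inside the sum.

All censored sums are evaluated with log-sum-exp over the log-pmf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import SurvivalData
from .distributions import DiscreteEventDistribution
from .exceptions import EmptySumError, RangeError

__all__ = [
    "centime_censored_logprob",
    "centime_censoring_marginal",
    "classical_censored_logprob",
    "classical_uncensored_logprob",
    "dataset_loglik",
    "DatasetLogLik",
]


def centime_censored_logprob(dist: DiscreteEventDistribution, c: int) -> float:
    """log p(C=c|x) under event-conditional censoring.

    Requires 1 <= c <= Tmax-1; c = Tmax leaves no admissible death time and
    raises :class:`EmptySumError`.
    """
    t_max = dist.grid.t_max
    c = int(c)
    if c < 1:
        raise RangeError(f"censoring time c={c} below grid start 1")
    if c >= t_max:
        raise EmptySumError(
            f"censoring time c={c} admits no death time t in {c + 1}..{t_max}; "
            "raise Tmax"
        )
    t = dist.grid.times[c:]  # t = c+1 .. Tmax
    return float(logsumexp(dist.log_pmf[c:] - np.log(t - 1)))


def centime_censoring_marginal(dist: DiscreteEventDistribution) -> np.ndarray:
    """The vector p(C=c|x) for c = 1..Tmax-1.

    Sums to 1 - p(D=1|x): a subject dying in the first month admits no
    censoring time.
    """
    t_max = dist.grid.t_max
    w = dist.pmf[1:] / (dist.grid.times[1:] - 1)  # p(t)/(t-1), t = 2..Tmax
    # entry c is sum_{t>c} w_t: reversed cumulative sum
    return np.cumsum(w[::-1])[::-1][: t_max - 1]


def classical_censored_logprob(
    dist: DiscreteEventDistribution, c: int, include_constant: bool = True
) -> float:
    """log p(delta=0, C=c|x) under independent uniform censoring.

    With ``include_constant=False`` the additive -log Tmax is dropped (the
    training-objective form). c = Tmax has zero probability under the
    classical mechanism; it returns -inf with a warning rather than raising,
    so a degenerate record cannot crash a fit.
    """
    t_max = dist.grid.t_max
    c = int(c)
    if not 1 <= c <= t_max:
        raise RangeError(f"censoring time c={c} outside grid 1..{t_max}")
    if c == t_max:
        warnings.warn(
            "classical censored likelihood at c=Tmax is an empty sum (log 0)",
            RuntimeWarning,
            stacklevel=2,
        )
        return -np.inf
    out = float(logsumexp(dist.log_pmf[c:]))
    if include_constant:
        out -= np.log(t_max)
    return out


def classical_uncensored_logprob(
    dist: DiscreteEventDistribution, t: int, include_constant: bool = True
) -> float:
    """log p(delta=1, D=t|x) = log[(Tmax-t+1)/Tmax * p(D=t|x)].

    ``include_constant=False`` drops the (Tmax-t+1)/Tmax factor, leaving the
    plain log p(D=t|x) used in the training objective.
    """
    t_max = dist.grid.t_max
    t = dist.grid.validate_time(t)
    out = float(dist.log_pmf[t - 1])
    if include_constant:
        out += np.log(t_max - t + 1) - np.log(t_max)
    return out


@dataclass(frozen=True)
class DatasetLogLik:
    """Dataset log-likelihood, total and per-observation mean."""

    total: float
    mean: float
    n: int


def dataset_loglik(
    data: SurvivalData,
    dists: list[DiscreteEventDistribution],
    model: str = "centime",
    include_constants: bool = False,
) -> DatasetLogLik:
    """The censored-data log-likelihood of a cohort.

    Sums log p(D=t_n|x_n) over uncensored subjects plus the model-specific
    censored term over censored subjects. ``model`` selects the censoring
    account ('centime' or 'classical'); ``include_constants`` switches the
    classical terms to their fully normalised probability form (it has no
    effect on the event-conditional model, whose terms are already
    probabilities).
    """
    if data.n == 0:
        raise ValueError("empty dataset has no likelihood")
    if len(dists) != data.n:
        raise ValueError(f"{len(dists)} distributions for {data.n} observations")
    if model not in ("centime", "classical"):
        raise ValueError(f"unknown likelihood model {model!r}")
    total = 0.0
    for i in range(data.n):
        d, t = dists[i], int(data.time[i])
        if data.status[i] == 1:
            if model == "classical" and include_constants:
                total += classical_uncensored_logprob(d, t)
            else:
                total += float(d.log_pmf[d.grid.validate_time(t) - 1])
        elif model == "centime":
            total += centime_censored_logprob(d, t)
        else:
            total += classical_censored_logprob(d, t, include_constant=include_constants)
    return DatasetLogLik(total=float(total), mean=float(total) / data.n, n=data.n)
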