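"""Cox proportional-hazards objectives, the memory-bank variant, and
Breslow-based death-time prediction.

The Cox model factorises the hazard as h(t|x) = h0(t) * exp(g(x)). The
partial log-likelihood used here is the uncensored-mean form

    L = (1/|Nuncens|) sum_{n in Nuncens} [ g_n - log sum_{m in R_n} exp(g_m) ],

with the risk set R_n = {m : time_m >= time_n} built from observed times for
censored and uncensored subjects alike (Breslow convention for ties). The
objective is invariant to adding a constant to every score.

Minibatch training evaluates the same objective within a batch; a batch with
no uncensored subject leaves it undefined and is signalled for exclusion
(``SKIP_BATCH``) rather than scored zero. The memory-bank variant (CoxMB)
enlarges both the anchor set and the risk sets with stored scores from
earlier iterations, so even an all-censored batch contributes: batch subjects
carry fresh scores wherever they appear, while bank scores enter as
constants. The bank bookkeeping here (latest score per subject, a fraction K
of eligible stored scores sampled without replacement per anchor, no decay)
is the simplest form consistent with the memory-bank literature.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy.special import logsumexp

from .distributions import TimeGrid
from .exceptions import UntrainableError

__all__ = [
    "SKIP_BATCH",
    "risk_set",
    "cox_relative_risk",
    "cox_partial_loglik",
    "cox_partial_loglik_grad",
    "minibatch_cox_loglik",
    "MemoryBank",
    "coxmb_loglik",
    "breslow_baseline_hazard",
    "cox_predict_time",
]


class _SkipBatch:
    """Sentinel: this batch has no uncensored subject; exclude it."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "SKIP_BATCH"

    def __bool__(self) -> bool:
        return False


SKIP_BATCH = _SkipBatch()


def risk_set(time: np.ndarray, anchor: int) -> np.ndarray:
    """Indices of subjects still at risk at subject ``anchor``'s time."""
    time = np.asarray(time)
    return np.flatnonzero(time >= time[anchor])


def cox_relative_risk(scores: np.ndarray, members: np.ndarray, anchor: int) -> float:
    """Relative death risk exp(g_anchor) / sum_{m in members} exp(g_m).

    ``anchor`` indexes into ``scores`` and must belong to ``members``.
    """
    scores = np.asarray(scores, dtype=float)
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("empty risk set")
    if anchor not in members:
        raise ValueError("anchor must belong to its own risk set")
    return float(np.exp(scores[anchor] - logsumexp(scores[members])))


def _check_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("risk scores must be finite")
    return scores


def cox_partial_loglik(scores, time, status) -> float:
    """Mean partial log-likelihood over uncensored subjects.

    Computed with a single reverse cumulative log-sum-exp sweep over subjects
    sorted by time (risk sets are nested), equivalent to the naive
    per-subject evaluation.
    """
    scores = _check_scores(scores)
    time = np.asarray(time)
    status = np.asarray(status)
    uncens = np.flatnonzero(status == 1)
    if uncens.size == 0:
        raise UntrainableError(
            "Cox partial likelihood is undefined without uncensored subjects"
        )
    order = np.argsort(time, kind="stable")
    s_sorted = scores[order]
    t_sorted = time[order]
    # suffix logsumexp: denom[i] = log sum_{j >= i} exp(s_sorted[j])
    m = np.max(s_sorted)
    suffix = np.log(np.cumsum(np.exp(s_sorted - m)[::-1])[::-1]) + m
    # ties share the denominator of the first index of their time group
    first_of_group = np.searchsorted(t_sorted, t_sorted, side="left")
    denom_sorted = suffix[first_of_group]
    denom = np.empty_like(denom_sorted)
    denom[order] = denom_sorted
    return float(np.mean(scores[uncens] - denom[uncens]))


def cox_partial_loglik_grad(scores, time, status, X) -> np.ndarray:
    """Gradient of :func:`cox_partial_loglik` w.r.t. beta for g = X @ beta."""
    scores = _check_scores(scores)
    time = np.asarray(time)
    status = np.asarray(status)
    X = np.asarray(X, dtype=float)
    uncens = np.flatnonzero(status == 1)
    if uncens.size == 0:
        raise UntrainableError("no uncensored subjects")
    order = np.argsort(time, kind="stable")
    s_sorted = scores[order]
    t_sorted = time[order]
    X_sorted = X[order]
    m = np.max(s_sorted)
    e = np.exp(s_sorted - m)
    denom = np.cumsum(e[::-1])[::-1]
    num = np.cumsum((e[:, None] * X_sorted)[::-1], axis=0)[::-1]
    first = np.searchsorted(t_sorted, t_sorted, side="left")
    expect_sorted = num[first] / denom[first][:, None]
    expect = np.empty_like(expect_sorted)
    expect[order] = expect_sorted
    return np.mean(X[uncens] - expect[uncens], axis=0)


def minibatch_cox_loglik(scores, time, status) -> Union[float, _SkipBatch]:
    """Within-batch partial log-likelihood, or ``SKIP_BATCH``.

    A batch containing no uncensored subject leaves the objective undefined;
    the sentinel (not zero) tells the training loop to exclude the batch.
    """
    status = np.asarray(status)
    if not np.any(status == 1):
        return SKIP_BATCH
    return cox_partial_loglik(scores, time, status)


class MemoryBank:
    """Per-subject store of the most recent risk score.

    One slot per training subject, refreshed whenever the subject appears in
    a batch; stored scores are treated as constants (no gradient flows
    through them) and are used as-is without staleness decay.
    """

    def __init__(self, time, status, usage_fraction: float = 1.0) -> None:
        if not 0.0 <= usage_fraction <= 1.0:
            raise ValueError(f"usage_fraction K must be in [0,1], got {usage_fraction}")
        self.time = np.asarray(time)
        self.status = np.asarray(status)
        self.usage_fraction = float(usage_fraction)
        n = len(self.time)
        self.scores = np.full(n, np.nan)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def initialised(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    def update(self, indices, new_scores) -> "MemoryBank":
        indices = np.asarray(indices, dtype=int)
        new_scores = np.asarray(new_scores, dtype=float)
        if indices.size and (indices.min() < 0 or indices.max() >= self.n):
            raise IndexError(f"subject index outside 0..{self.n - 1}")
        self.scores[indices] = new_scores
        return self


def coxmb_loglik(
    batch_indices,
    batch_scores,
    bank: MemoryBank,
    rng: np.random.Generator | None = None,
    return_grad: bool = False,
):
    """Memory-bank Cox objective for one minibatch.

    Anchors are the uncensored subjects of the pool formed by the batch
    (fresh scores) plus bank-stored subjects. Each anchor's risk set draws a
    fraction K of the eligible (time >= anchor time) non-batch bank slots,
    sampled without replacement, alongside the eligible batch members. With
    K=1 and batch = full data this reduces exactly to
    :func:`cox_partial_loglik`; with K=0 it reduces to the minibatch
    semantics including the skip-signal.

    With ``return_grad=True`` also returns d(objective)/d(batch_scores);
    bank-stored scores are constants, so gradient flows only through the
    fresh batch scores (including where they sit inside bank anchors' risk
    sets).
    """
    batch_indices = np.asarray(batch_indices, dtype=int)
    batch_scores = _check_scores(batch_scores)
    K = bank.usage_fraction
    rng = rng if rng is not None else np.random.default_rng(0)

    in_batch = np.zeros(bank.n, dtype=bool)
    in_batch[batch_indices] = True
    batch_pos = np.full(bank.n, -1)
    batch_pos[batch_indices] = np.arange(len(batch_indices))
    pool_scores = bank.scores.copy()
    pool_scores[batch_indices] = batch_scores

    outside = np.flatnonzero(~in_batch)
    # anchors: uncensored batch subjects always; uncensored bank subjects when the bank is in use
    anchor_idx = list(batch_indices[bank.status[batch_indices] == 1])
    if K > 0:
        bank_anchors = outside[bank.status[outside] == 1]
        if bank_anchors.size and np.any(np.isnan(bank.scores[bank_anchors])):
            raise ValueError("memory bank has uninitialised slots among eligible subjects")
        anchor_idx.extend(bank_anchors)
    if not anchor_idx:
        return (SKIP_BATCH, None) if return_grad else SKIP_BATCH

    terms = []
    dscores = np.zeros(len(batch_indices))
    for a in sorted(anchor_idx):
        elig_batch = batch_indices[bank.time[batch_indices] >= bank.time[a]]
        elig_bank = outside[bank.time[outside] >= bank.time[a]]
        if K > 0 and elig_bank.size:
            if np.any(np.isnan(bank.scores[elig_bank])):
                raise ValueError(
                    "memory bank has uninitialised slots among eligible subjects"
                )
            k = int(round(K * elig_bank.size))
            sampled = rng.choice(elig_bank, size=k, replace=False) if k else np.array([], int)
        else:
            sampled = np.array([], dtype=int)
        members = np.unique(np.concatenate([elig_batch, sampled, [a]]).astype(int))
        lse = logsumexp(pool_scores[members])
        terms.append(pool_scores[a] - lse)
        if return_grad:
            pi = np.exp(pool_scores[members] - lse)
            if in_batch[a]:
                dscores[batch_pos[a]] += 1.0
            mem_in_batch = in_batch[members]
            np.add.at(dscores, batch_pos[members[mem_in_batch]], -pi[mem_in_batch])
    value = float(np.mean(terms))
    if return_grad:
        return value, dscores / len(terms)
    return value


def breslow_baseline_hazard(scores, time, status, grid: TimeGrid) -> np.ndarray:
    """Breslow estimate of the cumulative baseline hazard H0 on the grid.

    H0(t) = sum over distinct event times t_k <= t of d_k / sum_{m in R_k} exp(g_m),
    with d_k the number of deaths at t_k.
    """
    scores = _check_scores(scores)
    time = np.asarray(time)
    status = np.asarray(status)
    if not np.any(status == 1):
        raise UntrainableError("Breslow baseline needs at least one uncensored subject")
    shift = np.max(scores)
    e = np.exp(scores - shift)
    event_times = np.unique(time[status == 1])
    increments = np.zeros(len(event_times))
    for k, tk in enumerate(event_times):
        d_k = np.sum((time == tk) & (status == 1))
        denom = np.sum(e[time >= tk])
        increments[k] = d_k / denom
    H0 = np.zeros(grid.t_max)
    for tk, inc in zip(event_times, increments):
        H0[grid.times >= tk] += inc
    return H0 * np.exp(-shift)


def cox_predict_time(
    scores,
    time,
    status,
    new_score: float,
    grid: TimeGrid,
    method: str = "median",
) -> float:
    """Predicted death time from a fitted Cox model.

    Builds the Breslow baseline from the training scores, forms the subject's
    survival curve S(t|x) = exp(-H0(t) exp(g)), and returns the first grid
    time where S drops to 0.5 (``median``, default; Tmax if never crossed) or
    the grid-restricted mean survival time 1 + sum_{t<Tmax} S(t) (``mean``).
    """
    H0 = breslow_baseline_hazard(scores, time, status, grid)
    S = np.exp(-H0 * np.exp(float(new_score)))
    if method == "median":
        below = np.flatnonzero(S <= 0.5)
        return float(grid.times[below[0]] if below.size else grid.t_max)
    if method == "mean":
        return float(1.0 + np.sum(S[:-1]))
    raise ValueError(f"unknown prediction method {method!r}; use 'median' or 'mean'")
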