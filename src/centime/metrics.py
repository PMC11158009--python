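"""Evaluation metrics: concordance index, MAE and RAE.

The C-index is the fraction of comparable pairs ordered correctly by the
model; a pair (i, j) is comparable when t_i < t_j and subject i is
uncensored (Harrell's rule — censored-first and censored-censored pairs are
not verifiable and are excluded, as are tied times). Tied predictions score
half a concordance (so an uninformative constant predictor lands at 0.5
rather than being undefined).

MAE and RAE average |t_hat - t| and |t_hat - t|/t over uncensored subjects
only; for censored subjects the true death time is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedMetricError

__all__ = ["concordance_index", "mae", "rae", "metrics_report", "MetricsReport"]


@dataclass(frozen=True)
class MetricsReport:
    """Bundle of evaluation metrics for one model/dataset pair."""

    c_index: float
    mae: float
    rae: float
    n_uncensored_evaluated: int
    n_pairs_evaluated: int

    def __str__(self) -> str:
        return (
            f"C-Index {self.c_index:.4f}  MAE {self.mae:.3f} months  "
            f"RAE {self.rae:.4f}  (n_uncensored={self.n_uncensored_evaluated}, "
            f"pairs={self.n_pairs_evaluated})"
        )


def concordance_index(predictions, time, status, direction: str = "risk") -> float:
    """Harrell's concordance index.

    ``direction='risk'`` treats a larger prediction as an earlier expected
    death (Cox-style risk scores); ``direction='time'`` treats a larger
    prediction as a later death (predicted survival times). Tied predictions
    count 0.5.
    """
    predictions = np.asarray(predictions, dtype=float)
    time = np.asarray(time)
    status = np.asarray(status)
    if direction == "risk":
        pass
    elif direction == "time":
        predictions = -predictions
    else:
        raise ValueError(f"unknown direction {direction!r}; use 'risk' or 'time'")
    comparable = (status[:, None] == 1) & (time[:, None] < time[None, :])
    n_pairs = int(np.sum(comparable))
    if n_pairs == 0:
        raise UndefinedMetricError("no comparable pairs: C-index undefined")
    diff = predictions[:, None] - predictions[None, :]
    concordant = np.sum(comparable & (diff > 0))
    tied = np.sum(comparable & (diff == 0))
    return float((concordant + 0.5 * tied) / n_pairs)


def _uncensored_abs_err(predicted_times, true_times, status):
    predicted = np.asarray(predicted_times, dtype=float)
    true = np.asarray(true_times, dtype=float)
    status = np.asarray(status)
    uncens = status == 1
    if not np.any(uncens):
        raise UndefinedMetricError("no uncensored subjects: error metric undefined")
    return np.abs(predicted[uncens] - true[uncens]), true[uncens]


def mae(predicted_times, true_times, status) -> float:
    """Mean absolute error (months) over uncensored subjects."""
    err, _ = _uncensored_abs_err(predicted_times, true_times, status)
    return float(np.mean(err))


def rae(predicted_times, true_times, status) -> float:
    """Mean relative absolute error |t_hat - t| / t over uncensored subjects."""
    err, true = _uncensored_abs_err(predicted_times, true_times, status)
    return float(np.mean(err / true))


def metrics_report(predicted_times, time, status, direction: str = "time") -> MetricsReport:
    """Compute all three metrics for time-scale predictions."""
    time = np.asarray(time)
    status = np.asarray(status)
    comparable = (status[:, None] == 1) & (time[:, None] < time[None, :])
    return MetricsReport(
        c_index=concordance_index(predicted_times, time, status, direction=direction),
        mae=mae(predicted_times, time, status),
        rae=rae(predicted_times, time, status),
        n_uncensored_evaluated=int(np.sum(status == 1)),
        n_pairs_evaluated=int(np.sum(comparable)),
    )
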