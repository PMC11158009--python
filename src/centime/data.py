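"""Survival datasets: covariates plus (status, time) per subject.

A record is either uncensored (status=1, time = observed death time t) or
right-censored (status=0, time = censoring time c, with the true death time
known only to exceed c). Times are integer months on the grid 1..Tmax.

Cohorts are stored as comma-delimited text with a header: free-form covariate
columns plus the fixed columns ``status`` and ``time``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = ["SurvivalData", "read_survival_table", "write_survival_table"]

STATUS_COL = "status"
TIME_COL = "time"


@dataclass(frozen=True)
class SurvivalData:
    """An immutable survival cohort.

    Attributes
    ----------
    X : (n, d) float array of covariates (d may be 0 for intercept-only data).
    status : (n,) int array, 1 = uncensored (death observed), 0 = censored.
    time : (n,) int array of months; death time when status=1, censoring
        time when status=0.
    covariate_names : names for the columns of ``X``.
    """

    X: np.ndarray
    status: np.ndarray
    time: np.ndarray
    covariate_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.size == 0:
            X = X.reshape(len(self.status), 0)
        status = np.asarray(self.status, dtype=int)
        time = np.asarray(self.time, dtype=int)
        n = len(status)
        if X.shape[0] != n or time.shape[0] != n:
            raise SchemaError(
                f"inconsistent lengths: X has {X.shape[0]} rows, "
                f"status {n}, time {time.shape[0]}"
            )
        names = tuple(self.covariate_names) or tuple(f"x{j + 1}" for j in range(X.shape[1]))
        if len(names) != X.shape[1]:
            raise SchemaError(f"{len(names)} covariate names for {X.shape[1]} columns")
        bad = np.flatnonzero(~np.isin(status, (0, 1)))
        if bad.size:
            raise SchemaError(f"status outside {{0,1}} in row {bad[0] + 1}")
        bad = np.flatnonzero(time < 1)
        if bad.size:
            raise SchemaError(f"time < 1 in row {bad[0] + 1}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "covariate_names", names)

    @property
    def n(self) -> int:
        return len(self.status)

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def uncensored_index(self) -> np.ndarray:
        """Indices n with status=1 (death time observed)."""
        return np.flatnonzero(self.status == 1)

    @property
    def censored_index(self) -> np.ndarray:
        return np.flatnonzero(self.status == 0)

    @property
    def n_uncensored(self) -> int:
        return int(np.sum(self.status == 1))

    def validate_for_grid(self, t_max: int, likelihood: str = "centime") -> None:
        """Check the cohort against a time grid and a likelihood's preconditions.

        Uncensored times must lie in 1..Tmax. Under the event-conditional
        (CenTime) likelihood a censored time c admits death times t > c, so
        c = Tmax leaves an empty sum; such records are rejected with advice to
        raise Tmax rather than silently producing -inf terms.
        """
        bad = np.flatnonzero(self.time > t_max)
        if bad.size:
            raise SchemaError(f"time > Tmax={t_max} in row {bad[0] + 1}")
        if likelihood == "centime":
            bad = np.flatnonzero((self.status == 0) & (self.time >= t_max))
            if bad.size:
                raise SchemaError(
                    f"censored time equals Tmax={t_max} in row {bad[0] + 1}: "
                    "no admissible death time remains under the "
                    "event-conditional likelihood; raise Tmax"
                )

    def subset(self, indices: Sequence[int]) -> "SurvivalData":
        idx = np.asarray(indices, dtype=int)
        return SurvivalData(
            self.X[idx], self.status[idx], self.time[idx], self.covariate_names
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SurvivalData":
        for col in (STATUS_COL, TIME_COL):
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        cov_cols = [c for c in df.columns if c not in (STATUS_COL, TIME_COL)]
        times = df[TIME_COL].to_numpy()
        frac = np.asarray(times, dtype=float)
        bad = np.flatnonzero(frac != np.round(frac))
        if bad.size:
            raise SchemaError(f"non-integer time in row {bad[0] + 1}")
        return cls(
            df[cov_cols].to_numpy(dtype=float) if cov_cols else np.empty((len(df), 0)),
            df[STATUS_COL].to_numpy(),
            np.round(frac).astype(int),
            tuple(cov_cols),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.covariate_names))
        df[STATUS_COL] = self.status
        df[TIME_COL] = self.time
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_survival_table(path) -> SurvivalData:
    """Read and validate a comma-delimited cohort file.

    The header must contain ``status`` and ``time``; every other column is
    taken as a covariate. Schema violations name the offending (1-based)
    data row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (ValueError, OSError) as exc:
        raise SchemaError(f"cannot read survival table {path}: {exc}") from exc
    return SurvivalData.from_dataframe(df)


def write_survival_table(data: SurvivalData, path) -> None:
    data.to_csv(path)
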