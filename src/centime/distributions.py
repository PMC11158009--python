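"""Discretised-Gaussian event-time distributions on an integer month grid.

The event model places a Gaussian density on the discrete grid 1..Tmax and
renormalises, giving

    p(D = t | x) = exp(-(t - mu)^2 / (2 sigma^2)) / Z,
    Z = sum_{t=1}^{Tmax} exp(-(t - mu)^2 / (2 sigma^2)).

All probability mass functions are computed in log space (max-subtraction
before exponentiation) so that extreme ``mu``/``sigma`` values never underflow
to an invalid log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .exceptions import InvalidParameterError, RangeError

__all__ = [
    "TimeGrid",
    "GaussianEventParams",
    "DiscreteEventDistribution",
    "discrete_gaussian",
    "gaussian_log_pmf",
    "event_cdf",
    "point_estimate",
]


@dataclass(frozen=True)
class TimeGrid:
    """The discrete time horizon: integer months 1..t_max inclusive."""

    t_max: int

    def __post_init__(self) -> None:
        if int(self.t_max) != self.t_max or self.t_max < 2:
            raise InvalidParameterError(f"t_max must be an integer >= 2, got {self.t_max}")
        object.__setattr__(self, "t_max", int(self.t_max))

    @property
    def times(self) -> np.ndarray:
        """The grid points 1..t_max as an integer array."""
        return np.arange(1, self.t_max + 1)

    def __len__(self) -> int:
        return self.t_max

    def validate_time(self, t: int, what: str = "time") -> int:
        t = int(t)
        if not 1 <= t <= self.t_max:
            raise RangeError(f"{what}={t} outside grid 1..{self.t_max}")
        return t


@dataclass(frozen=True)
class GaussianEventParams:
    """Location and scale (in months) of the discretised Gaussian.

    ``mu`` is an unconstrained real and may lie outside the grid; the
    normalisation over 1..Tmax absorbs this, so no clamping is applied.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise InvalidParameterError(f"mu must be finite, got {self.mu}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise InvalidParameterError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class DiscreteEventDistribution:
    """A normalised probability mass function over a :class:`TimeGrid`.

    ``log_pmf`` is the canonical representation; ``pmf`` is derived from it.
    Entry ``k`` (0-based index ``k-1``) is p(D = k | x).
    """

    grid: TimeGrid
    log_pmf: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        lp = np.asarray(self.log_pmf, dtype=float)
        if lp.shape != (self.grid.t_max,):
            raise InvalidParameterError(
                f"log_pmf has shape {lp.shape}, expected ({self.grid.t_max},)"
            )
        object.__setattr__(self, "log_pmf", lp)

    @classmethod
    def from_log_weights(cls, grid: TimeGrid, log_weights: np.ndarray) -> "DiscreteEventDistribution":
        """Normalise unnormalised log weights into a distribution."""
        lw = np.asarray(log_weights, dtype=float)
        return cls(grid, lw - logsumexp(lw))

    @classmethod
    def from_pmf(cls, grid: TimeGrid, pmf: np.ndarray) -> "DiscreteEventDistribution":
        pmf = np.asarray(pmf, dtype=float)
        if np.any(pmf < 0):
            raise InvalidParameterError("pmf entries must be non-negative")
        with np.errstate(divide="ignore"):
            return cls.from_log_weights(grid, np.log(pmf))

    @property
    def pmf(self) -> np.ndarray:
        return np.exp(self.log_pmf)

    def cdf(self, t: int) -> float:
        """Cumulative probability F(t) = sum_{k<=t} p(D = k)."""
        t = self.grid.validate_time(t)
        return float(np.sum(self.pmf[:t]))

    def mean(self) -> float:
        return float(self.pmf @ self.grid.times)

    def mode(self) -> int:
        """Most probable time; ties broken to the smallest index."""
        return int(self.grid.times[int(np.argmax(self.pmf))])

    def point_estimate(self, method: str = "mean") -> float:
        if method == "mean":
            return self.mean()
        if method == "mode":
            return float(self.mode())
        raise ValueError(f"unknown point-estimate method {method!r}; use 'mean' or 'mode'")


def gaussian_log_pmf(mu, sigma: float, grid: TimeGrid) -> np.ndarray:
    """Log-pmf rows of the discretised Gaussian, vectorised over ``mu``.

    Returns shape ``(Tmax,)`` for scalar ``mu`` or ``(n, Tmax)`` for a vector.
    """
    if not (np.isfinite(sigma) and sigma > 0):
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    mu = np.asarray(mu, dtype=float)
    t = grid.times.astype(float)
    f = -((t - mu[..., None]) ** 2) / (2.0 * sigma**2)
    return f - logsumexp(f, axis=-1, keepdims=True)


def discrete_gaussian(params: GaussianEventParams, grid: TimeGrid) -> DiscreteEventDistribution:
    """The discretised Gaussian event distribution on ``grid``."""
    return DiscreteEventDistribution(grid, gaussian_log_pmf(params.mu, params.sigma, grid))


def event_cdf(dist: DiscreteEventDistribution, t: int) -> float:
    """Functional alias for :meth:`DiscreteEventDistribution.cdf`."""
    return dist.cdf(t)


def point_estimate(dist: DiscreteEventDistribution, method: str = "mean") -> float:
    """Collapse a distribution to a predicted death time (months).

    ``mean`` (default) uses the full shape of the distribution; ``mode``
    returns the most probable grid time, ties broken to the smallest index.
    """
    return dist.point_estimate(method)
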