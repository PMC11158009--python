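"""Exception types shared across the package."""


class CenTimeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CenTimeError, ValueError):
    """A distribution or model parameter violates its domain (e.g. sigma <= 0)."""


class RangeError(CenTimeError, ValueError):
    """A time index lies outside the discrete grid."""


class EmptySumError(CenTimeError, ValueError):
    """A censored-likelihood sum has no admissible death times (c >= Tmax)."""


class SchemaError(CenTimeError, ValueError):
    """A survival table violates the expected column/value schema."""


class UndefinedMetricError(CenTimeError, ValueError):
    """A metric has no comparable pairs / no uncensored subjects to evaluate."""


class UntrainableError(CenTimeError, RuntimeError):
    """An objective is undefined on the given data.

    The Cox partial likelihood sums over uncensored subjects only, so it is
    untrainable on an all-censored dataset.
    """
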