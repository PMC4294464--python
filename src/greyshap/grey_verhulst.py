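"""Grey Verhulst model for saturating annual series.

The grey Verhulst model fits the logistic (Verhulst) differential equation

    dx1/dt + a * x1 = mu * x1**2

to a short time series through its discretised grey form

    x0(k) + a * z1(k) = mu * z1(k)**2,

where ``x1`` is the accumulated sequence, ``x0`` its first differences
and ``z1`` the consecutive-neighbour mean of ``x1``.  ``a`` is the
development coefficient (1/year) and ``mu`` the grey action quantity;
the saturation level of the dynamics is ``a / mu``.

Two orientations are supported:

``observed_as_accumulated`` (default)
    The observed series itself plays the role of the accumulated sequence
    ``x1`` — the convention appropriate for a series that is already
    S-shaped/saturating, like an annual fatality count.  Fitted values are
    the whitened time response evaluated at integer indices.

``classic_ago``
    The textbook grey convention: the observed series is cumulatively
    summed (AGO) to form ``x1``, fitted in accumulated space, and fitted
    values are recovered by first differencing (IAGO).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, EvaluationError, ValidationError
from .series import AnnualSeries

__all__ = [
    "Orientation",
    "DifferenceSequence",
    "MeanSequence",
    "GreyVerhulstFit",
    "ago",
    "iago",
    "mean_sequence",
    "fit",
    "time_response",
    "forecast",
]


class Orientation(str, enum.Enum):
    """How the observed series maps onto the accumulated sequence."""

    OBSERVED_AS_ACCUMULATED = "observed_as_accumulated"
    CLASSIC_AGO = "classic_ago"

    @classmethod
    def coerce(cls, value: "Orientation | str") -> "Orientation":
        if isinstance(value, cls):
            return value
        aliases = {"paper": cls.OBSERVED_AS_ACCUMULATED, "classic": cls.CLASSIC_AGO}
        if value in aliases:
            return aliases[value]
        return cls(value)


@dataclass(frozen=True)
class DifferenceSequence:
    """First differences of a series, with the first element retained.

    Layout: element 1 is the source's first value; element k (k >= 2) is
    value(k) - value(k-1).  Cumulative summation restores the source
    exactly, so this is the exact inverse of :func:`ago`.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    def accumulate(self) -> np.ndarray:
        """Undo the differencing (AGO): cumulative sum restores the source."""
        return np.cumsum(self.values)


@dataclass(frozen=True)
class MeanSequence:
    """Consecutive-neighbour means z(k) = (x(k) + x(k-1)) / 2, k = 2..n."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))


def ago(values: np.ndarray) -> np.ndarray:
    """Accumulated generating operation: cumulative sum."""
    return np.cumsum(np.asarray(values, dtype=np.float64))


def iago(series: AnnualSeries) -> DifferenceSequence:
    """Inverse accumulated generating operation (first differencing)."""
    if len(series) < 2:
        raise ValidationError("iago needs a series of length >= 2")
    values = np.concatenate(([series.values[0]], np.diff(series.values)))
    return DifferenceSequence(values)


def mean_sequence(series: AnnualSeries) -> MeanSequence:
    """Consecutive-neighbour mean sequence of a series (length n - 1)."""
    if len(series) < 2:
        raise ValidationError("mean_sequence needs a series of length >= 2")
    v = series.values
    return MeanSequence((v[1:] + v[:-1]) / 2.0)


@dataclass(frozen=True)
class GreyVerhulstFit:
    """Estimated grey Verhulst parameters and in-sample fitted values.

    Attributes
    ----------
    a:
        Development coefficient (1/year); positive for a declining series.
    mu:
        Grey action quantity; ``a / mu`` is the saturation level.
    anchor:
        x1(0), the first accumulated value.  The time response at index 0
        returns it exactly.
    orientation:
        Which accumulation convention produced the fit.
    fitted:
        Model values on the training years, in the observed scale.
    n:
        Number of training years.
    """

    a: float
    mu: float
    anchor: float
    orientation: Orientation
    fitted: AnnualSeries
    n: int

    @property
    def saturation(self) -> float:
        return self.a / self.mu


def _solve_parameters(z: np.ndarray, x0_response: np.ndarray) -> tuple[float, float]:
    # Design of the discretised equation: [-z, z^2] @ (a, mu) = x0.
    # QR-based lstsq; a rank-deficient 2-column design means the mean
    # sequence is (proportional to) constant and the dynamics are
    # unidentifiable.
    design = np.column_stack([-z, z**2])
    solution, _, rank, _ = np.linalg.lstsq(design, x0_response, rcond=None)
    if rank < 2:
        raise DegenerateFitError(
            "singular grey Verhulst system: the neighbour-mean sequence carries "
            "no curvature (e.g. constant input series)"
        )
    return float(solution[0]), float(solution[1])


def fit(
    series: AnnualSeries,
    orientation: Orientation | str = Orientation.OBSERVED_AS_ACCUMULATED,
) -> GreyVerhulstFit:
    """Fit the grey Verhulst model to an observed annual series.

    The two parameters minimise the squared residual of
    ``x0(k) + a * z1(k) = mu * z1(k)**2`` over k = 2..n, solved as a
    dense least-squares problem (QR).  The anchor is the first
    accumulated value and fitted values come from :func:`time_response`.
    """
    orientation = Orientation.coerce(orientation)
    series.require_observations()

    if orientation is Orientation.OBSERVED_AS_ACCUMULATED:
        x1 = series.values
    else:
        x1 = ago(series.values)
    accumulated = AnnualSeries(series.years, x1)

    z = mean_sequence(accumulated).values
    x0 = iago(accumulated).values[1:]  # differenced response, k = 2..n
    a, mu = _solve_parameters(z, x0)

    partial = GreyVerhulstFit(
        a=a, mu=mu, anchor=float(x1[0]), orientation=orientation,
        fitted=series, n=len(series),
    )
    x1_hat = np.array([time_response(partial, k) for k in range(len(series))])
    if orientation is Orientation.OBSERVED_AS_ACCUMULATED:
        fitted_values = x1_hat
    else:
        fitted_values = np.concatenate(([x1_hat[0]], np.diff(x1_hat)))
    fitted = AnnualSeries(series.years, fitted_values)
    return GreyVerhulstFit(
        a=a, mu=mu, anchor=float(x1[0]), orientation=orientation,
        fitted=fitted, n=len(series),
    )


def time_response(fit: GreyVerhulstFit, k: int) -> float:
    """Whitened time-response value x1_hat(k+1) at integer index k >= 0.

    Evaluates ``a*x1(0) / (mu*x1(0) + (a - mu*x1(0)) * exp(a*k))``;
    index 0 returns the anchor exactly.
    """
    if k < 0:
        raise ValidationError("time response index must be >= 0")
    a, mu, x0 = fit.a, fit.mu, fit.anchor
    denominator = mu * x0 + (a - mu * x0) * math.exp(a * k)
    if denominator == 0 or not math.isfinite(denominator):
        raise EvaluationError(f"time response denominator vanishes at k={k}")
    value = a * x0 / denominator
    if not math.isfinite(value):
        raise EvaluationError(f"time response not finite at k={k}")
    return value


def forecast(fit: GreyVerhulstFit, horizon: int) -> AnnualSeries:
    """Out-of-sample forecast for ``horizon`` years past the training range.

    Continues the in-sample index: the j-th year past the sample
    (j = 1..horizon) is the time response at k = n + j - 1, i.e. year
    ``first_year + n + j - 1`` maps to index ``n + j - 1``.  Under
    ``classic_ago`` the accumulated response is differenced back.
    """
    if horizon < 1:
        raise ValidationError("forecast horizon must be >= 1")
    first_year = fit.fitted.first_year
    years = first_year + fit.n + np.arange(horizon)
    if fit.orientation is Orientation.OBSERVED_AS_ACCUMULATED:
        values = np.array([time_response(fit, fit.n + j) for j in range(horizon)])
    else:
        # difference the accumulated trajectory, seeded by the last
        # in-sample accumulated value
        x1 = np.array([time_response(fit, fit.n - 1 + j) for j in range(horizon + 1)])
        values = np.diff(x1)
    return AnnualSeries(years, values)
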