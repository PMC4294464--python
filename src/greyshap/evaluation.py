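"""Residual testing: per-year relative errors and the comprehensive error.

The single-number accuracy summary used throughout the package is the
*comprehensive error*: the arithmetic mean of the per-year absolute
relative errors (in percent).  For a grey Verhulst fit the first year is
exact by construction (the time response anchors there), so its zero
error is conventionally excluded from the mean; regression and combined
fits average all years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EvaluationError, ValidationError
from .series import AnnualSeries

__all__ = ["ErrorReport", "relative_errors", "comprehensive_error"]


@dataclass(frozen=True)
class ErrorReport:
    """Per-year absolute and relative prediction errors.

    ``included`` marks the years that enter the comprehensive-error mean;
    it defaults to all years and is narrowed by
    :func:`comprehensive_error` when the anchor year is excluded.
    """

    years: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    absolute_errors: np.ndarray  # persons
    relative_errors: np.ndarray  # percent, >= 0
    included: np.ndarray  # bool mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "observed": self.observed,
                "predicted": self.predicted,
                "relative_error_pct": self.relative_errors,
            }
        )


def relative_errors(observed: AnnualSeries, predicted: AnnualSeries) -> ErrorReport:
    """Absolute and relative (%) errors of a prediction against observations.

    relative error(k) = |observed(k) - predicted(k)| / observed(k) * 100.
    """
    observed.assert_aligned(predicted)
    if np.any(observed.values == 0):
        bad = observed.years[observed.values == 0]
        raise EvaluationError(f"zero observed value in years {bad.tolist()}")
    absolute = np.abs(observed.values - predicted.values)
    relative = absolute / np.abs(observed.values) * 100.0
    return ErrorReport(
        years=observed.years.copy(),
        observed=observed.values.copy(),
        predicted=predicted.values.copy(),
        absolute_errors=absolute,
        relative_errors=relative,
        included=np.ones(len(observed), dtype=bool),
    )


def comprehensive_error(report: ErrorReport, exclude_anchor: bool = False) -> float:
    """Mean of the included relative errors, in percent.

    With ``exclude_anchor`` the first year of the report — exact by
    construction for an anchored grey Verhulst fit — is dropped from the
    mean (e.g. a 10-year fit averages the 9 later years).
    """
    mask = report.included.copy()
    if exclude_anchor:
        mask[0] = False
    if not mask.any():
        raise ValidationError("no years left in the comprehensive-error mean")
    return float(report.relative_errors[mask].mean())
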