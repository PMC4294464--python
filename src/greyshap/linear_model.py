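"""Six-covariate linear regression of annual fatalities.

Ordinary least squares with intercept of the death toll on six
macroscopic exposure covariates (vehicle population, population, GDP,
road freight volume, road passenger volume, road mileage), together with
the standard small-sample diagnostics: per-coefficient standard errors,
t values and two-sided p-values at the residual degrees of freedom,
R-squared, the multiple correlation R and the overall F statistic.

Fitting is delegated to :mod:`statsmodels` (QR-based, numerically stable
for the strongly collinear covariates this panel exhibits); this module
owns validation, the domain containers and the reporting conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .errors import DegenerateFitError, ValidationError
from .series import PANEL_COLUMNS, AnnualSeries, CovariatePanel

__all__ = ["RegressionFit", "CorrelationReport", "correlation_table", "fit_ols", "predict"]

_TERMS = ("intercept", *PANEL_COLUMNS)


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation of each covariate with the response.

    The covariates all trend upward while fatalities fall, so the signed
    correlations are negative; the conventional report shows magnitudes.
    """

    signed: pd.Series  # index = covariate names
    magnitude: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"signed": self.signed, "magnitude": self.magnitude})


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit: coefficients, small-sample diagnostics, fitted values."""

    params: pd.Series  # intercept + six slopes, index = _TERMS
    std_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series  # two-sided, t distribution at df_resid
    r_squared: float
    multiple_r: float
    f_statistic: float
    df_model: int
    df_resid: int
    fitted: AnnualSeries

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "std_error": self.std_errors,
                "t_value": self.t_values,
                "significance": self.p_values,
            }
        )


def correlation_table(panel: CovariatePanel, response: AnnualSeries) -> CorrelationReport:
    """Pearson correlation of each panel column with the response."""
    panel.assert_aligned(response)
    if len(response) < 3:
        raise ValidationError("correlation needs at least 3 observations")
    signed = {}
    y = response.values
    for column in PANEL_COLUMNS:
        x = panel.frame[column].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0:
            raise ValidationError(f"column {column!r} has zero variance; correlation undefined")
        signed[column] = float(np.corrcoef(x, y)[0, 1])
    signed_series = pd.Series(signed, name="signed")
    return CorrelationReport(signed=signed_series, magnitude=signed_series.abs())


def _collinear_columns(design: np.ndarray) -> list[str]:
    # pivoted QR: pivots beyond the numerical rank name the columns that
    # add no independent information
    _, r, pivots = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(np.float64).eps
    rank = int((diag > tol).sum())
    return [_TERMS[i] for i in sorted(pivots[rank:])]


def fit_ols(panel: CovariatePanel, response: AnnualSeries) -> RegressionFit:
    """Fit fatalities on the six covariates by least squares with intercept.

    Requires more rows than the seven parameters so the residual degrees
    of freedom are positive; a rank-deficient design raises
    ``DegenerateFitError`` naming the collinear columns.
    """
    panel.assert_aligned(response)
    n, p = len(response), len(PANEL_COLUMNS)
    if n <= p + 1:
        raise ValidationError(
            f"need more than {p + 1} rows to fit {p + 1} parameters, got {n}"
        )
    design = sm.add_constant(panel.matrix(), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateFitError(
            f"rank-deficient design; collinear columns: {_collinear_columns(design)}"
        )
    result = sm.OLS(response.values, design).fit()
    index = pd.Index(_TERMS)
    return RegressionFit(
        params=pd.Series(result.params, index=index),
        std_errors=pd.Series(result.bse, index=index),
        t_values=pd.Series(result.tvalues, index=index),
        p_values=pd.Series(result.pvalues, index=index),
        r_squared=float(result.rsquared),
        multiple_r=float(np.sqrt(result.rsquared)),
        f_statistic=float(result.fvalue),
        df_model=int(result.df_model),
        df_resid=int(result.df_resid),
        fitted=AnnualSeries(response.years, result.fittedvalues),
    )


def predict(fit: RegressionFit, panel: CovariatePanel) -> AnnualSeries:
    """Apply the fitted equation to a covariate panel (any years)."""
    values = fit.params["intercept"] + panel.matrix() @ fit.params[list(PANEL_COLUMNS)].to_numpy()
    return AnnualSeries(panel.years, values)
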