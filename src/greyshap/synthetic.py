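"""Seeded generators for inputs with the structure the models assume.

``generate_logistic`` samples the continuous Verhulst solution

    x1(t) = a * x0 / (mu * x0 + (a - mu * x0) * exp(a * t))

at integer years, optionally perturbed by multiplicative Gaussian noise
(relative noise is the natural choice because relative error is the
evaluation currency downstream).  ``generate_panel`` builds a covariate
panel with geometric per-column growth — mimicking the joint upward
drift of real exposure covariates — and a response that is exactly
linear in the covariates plus additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .series import PANEL_COLUMNS, AnnualSeries, CovariatePanel

__all__ = ["LogisticSpec", "PanelSpec", "generate_logistic", "generate_panel"]


@dataclass(frozen=True)
class LogisticSpec:
    """Parameters of a synthetic saturating (Verhulst) annual series."""

    a: float = 0.12238288
    mu: float = 6.894770e-07
    x0: float = 109381.0
    n: int = 10
    first_year: int = 2002
    noise: float = 0.0  # relative (multiplicative) std dev
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x0 <= 0:
            raise ValidationError("x0 must be positive")
        if self.n < 4:
            raise ValidationError("need at least 4 years")
        if self.noise < 0:
            raise ValidationError("noise level must be >= 0")


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a synthetic covariate panel and linear response.

    Defaults echo the magnitudes of the real study panel: six covariates
    starting near their 2002 values and growing a few percent a year,
    with a response of order 1e5 and noise of a few hundred persons.
    """

    intercept: float = 120000.0
    slopes: tuple[float, ...] = (-9.0, -5.0, -0.15, 0.09, -0.03, 0.003)
    col_starts: tuple[float, ...] = (2000.0, 128000.0, 120000.0, 1.1e6, 1.5e6, 1.8e6)
    col_growth: tuple[float, ...] = (0.18, 0.005, 0.16, 0.11, 0.09, 0.10)
    noise_sd: float = 500.0
    n: int = 10
    first_year: int = 2002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValidationError("need at least 8 years for a 7-parameter fit")
        if not (len(self.slopes) == len(self.col_starts) == len(self.col_growth) == 6):
            raise ValidationError("exactly six slopes, starts and growth rates required")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def generate_logistic(spec: LogisticSpec) -> AnnualSeries:
    """Sample the continuous Verhulst trajectory, with optional noise."""
    t = np.arange(spec.n, dtype=np.float64)
    denom = spec.mu * spec.x0 + (spec.a - spec.mu * spec.x0) * np.exp(spec.a * t)
    values = spec.a * spec.x0 / denom
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        values = values * (1.0 + spec.noise * rng.standard_normal(spec.n))
        values = np.maximum(values, np.finfo(np.float64).tiny)
    return AnnualSeries(spec.first_year + np.arange(spec.n), values)


def generate_panel(spec: PanelSpec) -> tuple[CovariatePanel, AnnualSeries]:
    """Geometric-trend covariates plus a linear-with-noise response."""
    import pandas as pd

    t = np.arange(spec.n, dtype=np.float64)
    columns = {
        name: start * (1.0 + growth) ** t
        for name, start, growth in zip(PANEL_COLUMNS, spec.col_starts, spec.col_growth)
    }
    years = spec.first_year + np.arange(spec.n)
    frame = pd.DataFrame({"year": years, **columns})
    panel = CovariatePanel(frame)
    response = spec.intercept + panel.matrix() @ np.asarray(spec.slopes)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        response = response + spec.noise_sd * rng.standard_normal(spec.n)
    return panel, AnnualSeries(years, response)
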