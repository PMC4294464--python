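"""Year-indexed containers: annual observation series and covariate panels.

The two containers here are deliberately thin wrappers over numpy/pandas.
``AnnualSeries`` is the common currency of the whole package: observed
fatality counts, fitted model values, forecasts and combined predictions
are all annual series over consecutive calendar years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError, ValidationError

__all__ = ["AnnualSeries", "CovariatePanel", "PANEL_COLUMNS"]

#: Covariate columns, in the order the regression model uses them:
#: vehicle population (1e4 vehicles), population (1e4 persons), GDP
#: (1e8 yuan), road freight volume (1e4 t), road passenger volume
#: (1e4 persons), road mileage (km).
PANEL_COLUMNS = (
    "vehicles_1e4",
    "population_1e4",
    "gdp_1e8",
    "freight_1e4t",
    "passengers_1e4",
    "road_km",
)


@dataclass(frozen=True)
class AnnualSeries:
    """A vector of real values indexed by consecutive calendar years.

    Parameters
    ----------
    years:
        Strictly increasing, consecutive integers (step 1).
    values:
        Real values, one per year.  Observed death tolls must be positive;
        that stricter invariant is enforced by :meth:`require_observations`
        at the points where a series is used as model input, so that model
        *output* series (forecasts, residual-like quantities) can use the
        same container.
    """

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1:
            raise ValidationError("years and values must be 1-dimensional")
        if len(years) != len(values):
            raise ValidationError(
                f"length mismatch: {len(years)} years vs {len(values)} values"
            )
        if len(years) == 0:
            raise ValidationError("series must contain at least one year")
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise ValidationError("years must be consecutive (step 1)")
        if not np.all(np.isfinite(values)):
            raise ValidationError("series values must be finite")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.years)

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    def value_for(self, year: int) -> float:
        if not self.first_year <= year <= self.last_year:
            raise KeyError(f"year {year} outside [{self.first_year}, {self.last_year}]")
        return float(self.values[year - self.first_year])

    # -- invariants for *observed* input series ---------------------------
    def require_observations(self, min_length: int = 4) -> "AnnualSeries":
        """Validate the stricter invariants of an observed death-toll series.

        Grey Verhulst dynamics assume positive states, and a two-parameter
        fit needs at least four points; violations raise ``ValidationError``.
        """
        if len(self) < min_length:
            raise ValidationError(
                f"observed series needs >= {min_length} years, got {len(self)}"
            )
        if np.any(self.values <= 0):
            bad = self.years[self.values <= 0]
            raise ValidationError(f"non-positive observations in years {bad.tolist()}")
        return self

    # -- conversions -------------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, value_column: str = "deaths") -> "AnnualSeries":
        if "year" not in frame.columns or value_column not in frame.columns:
            raise SchemaError(
                f"expected columns ('year', {value_column!r}), got {list(frame.columns)}"
            )
        return cls(frame["year"].to_numpy(), frame[value_column].to_numpy())

    def to_frame(self, value_column: str = "deaths") -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, value_column: self.values})

    def rounded(self) -> np.ndarray:
        """Values rounded to the nearest integer (deaths are counts)."""
        return np.rint(self.values).astype(np.int64)

    def assert_aligned(self, other: "AnnualSeries") -> None:
        if len(self) != len(other) or not np.array_equal(self.years, other.years):
            raise AlignmentError(
                f"year ranges differ: {self.first_year}-{self.last_year} vs "
                f"{other.first_year}-{other.last_year}"
            )


@dataclass(frozen=True)
class CovariatePanel:
    """Annual panel of the six macroscopic exposure covariates.

    Wraps a DataFrame with a ``year`` column plus the six columns of
    :data:`PANEL_COLUMNS`.  No missing cells are allowed.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        frame = self.frame.reset_index(drop=True)
        missing = [c for c in ("year", *PANEL_COLUMNS) if c not in frame.columns]
        if missing:
            raise SchemaError(f"panel is missing columns {missing}")
        frame = frame[["year", *PANEL_COLUMNS]].copy()
        try:
            frame = frame.astype(np.float64)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"panel contains non-numeric cells: {exc}") from exc
        if frame.isna().any().any():
            rows, cols = np.nonzero(frame.isna().to_numpy())
            cells = [(int(r), frame.columns[c]) for r, c in zip(rows, cols)]
            raise SchemaError(f"panel has missing cells at (row, column) {cells}")
        frame["year"] = frame["year"].astype(np.int64)
        if not frame["year"].is_monotonic_increasing or frame["year"].duplicated().any():
            raise ValidationError("panel years must be strictly increasing")
        object.__setattr__(self, "frame", frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def years(self) -> np.ndarray:
        return self.frame["year"].to_numpy()

    def matrix(self) -> np.ndarray:
        """The n x 6 covariate matrix in canonical column order."""
        return self.frame[list(PANEL_COLUMNS)].to_numpy(dtype=np.float64)

    def assert_aligned(self, response: AnnualSeries) -> None:
        if len(self) != len(response) or not np.array_equal(self.years, response.years):
            raise AlignmentError("panel years do not match the response series")
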