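"""CSV readers/writers and the bundled study fixtures.

All tabular I/O is comma-separated UTF-8 with a required header and
decimal points.  The study's printed tables are bundled as package data
and reachable by short fixture names, so the full pipeline runs without
any external file.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .evaluation import ErrorReport
from .series import AnnualSeries, CovariatePanel

__all__ = [
    "load_series",
    "load_panel",
    "write_series",
    "write_error_report",
    "load_fixture",
    "fixture_names",
]

_FIXTURES = {
    # inputs transcribed from the study's printed tables
    "table1": ("table1_fatalities.csv", "series"),
    "table3": ("table3_panel.csv", "panel"),
    "table9": ("table9_panel.csv", "panel"),
    "table9_observed": ("table9_fatalities.csv", "series"),
    "table10_members": ("table10_members.csv", "frame"),
    # printed outputs, used for reproduction pass/fail comparison
    "table2_printed": ("table2_printed.csv", "frame"),
    "table4_printed": ("table4_printed.csv", "frame"),
    "table5_printed": ("table5_printed.csv", "frame"),
    "table6_printed": ("table6_printed.csv", "frame"),
    "table8_printed": ("table8_printed.csv", "frame"),
}


def _read_csv(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if frame.empty:
        raise SchemaError(f"{path}: no data rows")
    return frame


def load_series(path: str | Path, value_column: str = "deaths") -> AnnualSeries:
    """Read an annual series CSV with header ``year,deaths``."""
    frame = _read_csv(path)
    if "year" not in frame.columns or value_column not in frame.columns:
        raise SchemaError(
            f"{path}: expected header 'year,{value_column}', got {list(frame.columns)}"
        )
    for col in ("year", value_column):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise SchemaError(f"{path}: non-numeric cell at row {row}, column {col!r}")
        frame[col] = numeric
    return AnnualSeries.from_frame(frame, value_column=value_column)


def load_panel(path: str | Path) -> CovariatePanel:
    """Read a covariate panel CSV (year plus the six covariate columns)."""
    return CovariatePanel(_read_csv(path))


def write_series(series: AnnualSeries, path: str | Path, value_column: str = "deaths") -> None:
    series.to_frame(value_column=value_column).to_csv(path, index=False)


def write_error_report(report: ErrorReport, path: str | Path, summary: float | None = None) -> None:
    """Write ``year,observed,predicted,relative_error_pct`` rows.

    If ``summary`` is given, a trailing comprehensive-error line is
    appended in the same style as the printed tables.
    """
    frame = report.to_frame()
    frame.to_csv(path, index=False)
    if summary is not None:
        with open(path, "a", encoding="utf-8") as handle:
            handle.write(f"comprehensive_error,,,{summary:.3f}\n")


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def load_fixture(name: str):
    """Load a bundled fixture by name.

    Input fixtures return domain objects (``AnnualSeries`` /
    ``CovariatePanel``); printed-output fixtures return plain DataFrames.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}")
    filename, kind = _FIXTURES[name]
    ref = resources.files("greyshap.data").joinpath(filename)
    with resources.as_file(ref) as path:
        frame = _read_csv(path)
    if kind == "series":
        return AnnualSeries.from_frame(frame)
    if kind == "panel":
        return CovariatePanel(frame)
    return frame
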