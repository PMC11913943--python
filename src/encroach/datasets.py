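"""Packaged desk-scale fixtures for the Bisley Nature Reserve case study.

These tables carry the published per-year class areas and the published
subset of per-interval transitions for a ~354 ha, three-class reserve
(woody vegetation, grasses, bare areas) observed in 2009, 2014, 2019 and
2023, plus the projected areas and transitions for 2028 and 2033.  Values
are printed to 2 decimals, so every reconstruction from them inherits that
rounding.

Two internal inconsistencies of the published tables are preserved as-is
and handled explicitly here rather than silently "fixed":

* Some percent-cover entries do not match their own hectare columns (most
  visibly the 2019 rows).  Loaders keep the hectares authoritative; the
  printed percents are kept in a separate column for reference.
* The 2019-2023 grasses->grasses transition (97.19 ha) is incompatible with
  the 2019/2023 grass marginals by ~17 ha, and 2014-2019 carries a ~1.2 ha
  column residual.  Only the 2009-2014 interval completes within the default
  0.5 ha tolerance; :func:`bisley_completed_matrices` therefore relaxes the
  tolerance per interval and reports the achieved residuals.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .change import TransitionMatrix, complete_matrix
from .grids import ClassScheme
from .synthetic import bisley_scheme

__all__ = [
    "load_bisley_areas",
    "load_bisley_transitions",
    "bisley_area_table",
    "bisley_partial_matrix",
    "bisley_completed_matrix",
    "bisley_completed_matrices",
    "OBSERVED_INTERVALS",
    "INTERVAL_DURATIONS",
]

OBSERVED_INTERVALS = ("2009-2014", "2014-2019", "2019-2023")
INTERVAL_DURATIONS = {
    "2009-2014": 5.0,
    "2014-2019": 5.0,
    "2019-2023": 4.0,
    "2009-2023": 14.0,
    "2023-2028": 5.0,
    "2028-2033": 5.0,
}

# Published-table residuals against the year marginals exceed the default
# completion tolerance for the later observed intervals (see module docstring).
_COMPLETION_TOL = {"2009-2014": 0.5, "2014-2019": 1.5, "2019-2023": 20.0}


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("encroach.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_bisley_areas() -> pd.DataFrame:
    """Per-year class areas (ha) with the published percent covers.

    Columns: ``year, class, area_ha, percent_cover_printed, status`` where
    status marks observed vs projected years.
    """
    return _read_csv("bisley_areas.csv")


def load_bisley_transitions() -> pd.DataFrame:
    """Published per-interval transition areas (six cells per interval, ha)."""
    return _read_csv("bisley_transitions.csv")


def bisley_area_table(status: str | None = None) -> pd.DataFrame:
    """Areas pivoted to years x classes (ha), in scheme order."""
    scheme = bisley_scheme()
    frame = load_bisley_areas()
    if status is not None:
        frame = frame[frame["status"] == status]
    table = frame.pivot(index="year", columns="class", values="area_ha")
    return table[list(scheme.names)]


def bisley_partial_matrix(interval: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, ClassScheme]:
    """The published partial matrix and year marginals for one interval.

    Returns ``(known, row_totals, col_totals, duration, scheme)`` with NaN
    marking the three unpublished cells (woody->bare, bare->woody, bare->bare).
    """
    scheme = bisley_scheme()
    transitions = load_bisley_transitions()
    rows = transitions[transitions["interval"] == interval]
    if rows.empty:
        raise KeyError(f"unknown interval {interval!r}")
    known = np.full((scheme.J, scheme.J), np.nan)
    for _, rec in rows.iterrows():
        known[scheme.names.index(rec["from"]), scheme.names.index(rec["to"])] = rec["area_ha"]
    areas = bisley_area_table()
    y0, y1 = (int(y) for y in interval.split("-"))
    row_totals = areas.loc[y0].to_numpy(dtype=float)
    col_totals = areas.loc[y1].to_numpy(dtype=float)
    return known, row_totals, col_totals, INTERVAL_DURATIONS[interval], scheme


def bisley_completed_matrix(interval: str, tol: float | None = None) -> TransitionMatrix:
    """Full 3x3 transition matrix reconstructed from the published cells.

    The three unpublished cells are solved from the year marginals by
    non-negative least squares.  ``tol`` defaults to an interval-specific
    tolerance that accommodates the published tables' internal residuals; the
    achieved residual is reported on the result.
    """
    known, row_totals, col_totals, duration, scheme = bisley_partial_matrix(interval)
    if tol is None:
        tol = _COMPLETION_TOL.get(interval, 0.5)
    return complete_matrix(known, row_totals, col_totals, duration=duration, scheme=scheme, tol=tol)


def bisley_completed_matrices() -> dict[str, TransitionMatrix]:
    """Completed matrices for the three observed intervals, keyed by interval."""
    return {interval: bisley_completed_matrix(interval) for interval in OBSERVED_INTERVALS}
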