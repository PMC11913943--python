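"""Change detection between categorical land-cover maps.

Cross-tabulates pairs of maps into area transition matrices (hectares),
completes partially known matrices from their row/column marginals, and
computes the net-change and percent-cover summaries that a change-detection
study reports.

A :class:`TransitionMatrix` follows the standard orientation: rows are the
class at the start of the interval, columns the class at the end, entries in
hectares.  Pixel area is ``pixel_size**2 / 10_000`` ha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .grids import AlignmentError, ClassScheme, InvalidInputError, LandCoverMap

__all__ = [
    "TransitionMatrix",
    "InconsistentMarginalsError",
    "crosstab",
    "complete_matrix",
    "change_summaries",
    "ChangeSummary",
    "relative_interval_change",
    "cover_point_change",
]


class InconsistentMarginalsError(InvalidInputError):
    """Marginal constraints cannot be satisfied within tolerance.

    Carries the worst constraint residual (hectares) in ``residual``.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True, eq=False)
class TransitionMatrix:
    """J x J area transition matrix for one time interval.

    ``entries[i, j]`` is the area (ha) moving from class ``i`` at the start of
    the interval to class ``j`` at the end; ``duration`` is the interval
    length in years.
    """

    entries: np.ndarray
    duration: float
    scheme: ClassScheme
    completion_residual: float | None = None
    n_nodata_excluded: int = 0

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        J = self.scheme.J
        if entries.shape != (J, J):
            raise InvalidInputError(f"entries must be {J}x{J}, got {entries.shape}")
        if np.any(entries < -1e-9):
            raise InvalidInputError("transition areas must be non-negative")
        if not (self.duration > 0):
            raise InvalidInputError("interval duration must be > 0")
        object.__setattr__(self, "entries", np.clip(entries, 0.0, None))
        object.__setattr__(self, "duration", float(self.duration))

    @property
    def total_area(self) -> float:
        return float(self.entries.sum())

    @property
    def row_totals(self) -> np.ndarray:
        """Class areas at the start of the interval."""
        return self.entries.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """Class areas at the end of the interval."""
        return self.entries.sum(axis=0)

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.entries)

    @property
    def gains(self) -> np.ndarray:
        """Gross gain per class: column sum minus diagonal."""
        return self.col_totals - self.diagonal

    @property
    def losses(self) -> np.ndarray:
        """Gross loss per class: row sum minus diagonal."""
        return self.row_totals - self.diagonal

    @property
    def change_area(self) -> float:
        """Total off-diagonal area (ha)."""
        return self.total_area - float(self.diagonal.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=list(self.scheme.names), columns=list(self.scheme.names))

    def write_csv(self, path: str | Path) -> Path:
        """Write entries as CSV plus a JSON sidecar with scheme and duration."""
        path = Path(path)
        self.to_frame().to_csv(path)
        sidecar = {
            "scheme": {"codes": list(self.scheme.codes), "names": list(self.scheme.names)},
            "duration": self.duration,
            "total_area": self.total_area,
            "completion_residual": self.completion_residual,
            "n_nodata_excluded": self.n_nodata_excluded,
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "TransitionMatrix":
        path = Path(path)
        frame = pd.read_csv(path, index_col=0)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            sidecar = json.load(fh)
        scheme = ClassScheme(
            codes=tuple(sidecar["scheme"]["codes"]), names=tuple(sidecar["scheme"]["names"])
        )
        return cls(
            entries=frame.to_numpy(dtype=float),
            duration=sidecar["duration"],
            scheme=scheme,
            completion_residual=sidecar.get("completion_residual"),
            n_nodata_excluded=sidecar.get("n_nodata_excluded", 0),
        )


def crosstab(map_t: LandCoverMap, map_t1: LandCoverMap, duration: float) -> TransitionMatrix:
    """Cross-tabulate two aligned maps into an area transition matrix.

    Cells that are nodata at either date are excluded; their count is
    reported on the result as ``n_nodata_excluded``.
    """
    if not map_t.grid.aligned(map_t1.grid):
        raise AlignmentError("maps are not aligned")
    if map_t.scheme != map_t1.scheme:
        raise InvalidInputError("maps use different class schemes")
    scheme = map_t.scheme
    valid = map_t.grid.valid_mask & map_t1.grid.valid_mask
    a = map_t.grid.values[valid]
    b = map_t1.grid.values[valid]
    code_to_idx = {code: k for k, code in enumerate(scheme.codes)}
    ia = np.vectorize(code_to_idx.get, otypes=[np.int64])(a) if a.size else np.empty(0, np.int64)
    ib = np.vectorize(code_to_idx.get, otypes=[np.int64])(b) if b.size else np.empty(0, np.int64)
    counts = np.zeros((scheme.J, scheme.J), dtype=np.int64)
    np.add.at(counts, (ia, ib), 1)
    pixel_area = map_t.grid.pixel_area_ha
    return TransitionMatrix(
        entries=counts * pixel_area,
        duration=duration,
        scheme=scheme,
        n_nodata_excluded=int((~valid).sum()),
    )


def complete_matrix(
    known: np.ndarray,
    row_totals: Sequence[float],
    col_totals: Sequence[float],
    duration: float = 1.0,
    scheme: ClassScheme | None = None,
    tol: float = 0.5,
) -> TransitionMatrix:
    """Complete a partially known transition matrix from its marginals.

    ``known`` is J x J with ``NaN`` marking unknown cells.  Unknowns are
    solved from the linear row/column-sum constraints; when the system is
    under- or over-determined it is solved by non-negative least squares.  The
    worst absolute constraint residual of the completed matrix is stored on
    the result (``completion_residual``); residuals beyond ``tol`` hectares
    raise :class:`InconsistentMarginalsError`.
    """
    known = np.asarray(known, dtype=float)
    row_totals = np.asarray(row_totals, dtype=float)
    col_totals = np.asarray(col_totals, dtype=float)
    J = known.shape[0]
    if known.shape != (J, J) or row_totals.shape != (J,) or col_totals.shape != (J,):
        raise InvalidInputError("known matrix and marginals have inconsistent shapes")
    if scheme is None:
        scheme = ClassScheme(
            codes=tuple(range(1, J + 1)), names=tuple(f"class {k}" for k in range(1, J + 1))
        )
    grand_mismatch = abs(row_totals.sum() - col_totals.sum())
    if grand_mismatch > max(tol, tol * J):
        raise InconsistentMarginalsError(
            f"row totals and column totals disagree by {grand_mismatch:.3f} ha",
            residual=float(grand_mismatch),
        )
    unknown = np.isnan(known)
    filled = known.copy()
    if unknown.any():
        idx = np.argwhere(unknown)
        n = len(idx)
        A = np.zeros((2 * J, n))
        b = np.zeros(2 * J)
        known_zeroed = np.where(unknown, 0.0, known)
        for r in range(J):
            b[r] = row_totals[r] - known_zeroed[r, :].sum()
            b[J + r] = col_totals[r] - known_zeroed[:, r].sum()
        for k, (r, c) in enumerate(idx):
            A[r, k] = 1.0
            A[J + c, k] = 1.0
        # Drop constraints with no unknown in them: they cannot inform the solve,
        # but they still count toward the reported residual below.
        active = A.any(axis=1)
        x, _ = nnls(A[active], b[active])
        filled[unknown] = x
    filled = np.clip(filled, 0.0, None)
    residual = float(
        max(
            np.abs(filled.sum(axis=1) - row_totals).max(),
            np.abs(filled.sum(axis=0) - col_totals).max(),
        )
    )
    if residual > tol:
        raise InconsistentMarginalsError(
            f"completed matrix violates marginals by {residual:.3f} ha (tol {tol} ha)",
            residual=residual,
        )
    return TransitionMatrix(
        entries=filled, duration=duration, scheme=scheme, completion_residual=residual
    )


@dataclass(frozen=True)
class ChangeSummary:
    """Headline change statistics across a multi-date series."""

    total_area: float
    net_change: pd.DataFrame        # per class: net ha and % of total area
    percent_cover: pd.DataFrame     # years x classes, % of that year's total
    transition_areas: pd.DataFrame | None  # tidy per-interval transition areas
    transition_percent: pd.DataFrame | None  # same, as % of total area


def change_summaries(
    areas_by_year: pd.DataFrame,
    matrices: Mapping[str, TransitionMatrix] | None = None,
) -> ChangeSummary:
    """Net change, percent cover and per-interval transition summaries.

    ``areas_by_year`` has one row per observation year and one column per
    class, in hectares.  Net change runs from the first to the last year and
    is also expressed as a percentage of the first year's total area.
    """
    if areas_by_year.empty:
        raise InvalidInputError("areas_by_year is empty")
    years = list(areas_by_year.index)
    total_area = float(areas_by_year.loc[years[0]].sum())
    net_ha = areas_by_year.loc[years[-1]] - areas_by_year.loc[years[0]]
    net = pd.DataFrame(
        {"net_change_ha": net_ha, "net_change_pct_of_area": net_ha / total_area * 100.0}
    )
    cover = areas_by_year.div(areas_by_year.sum(axis=1), axis=0) * 100.0
    tidy = None
    tidy_pct = None
    if matrices:
        records = []
        for interval, m in matrices.items():
            frame = m.to_frame()
            for i in frame.index:
                for j in frame.columns:
                    records.append(
                        {
                            "interval": interval,
                            "from": i,
                            "to": j,
                            "area_ha": frame.loc[i, j],
                            "pct_of_area": frame.loc[i, j] / total_area * 100.0,
                        }
                    )
        tidy = pd.DataFrame(records)[["interval", "from", "to", "area_ha"]]
        tidy_pct = pd.DataFrame(records)[["interval", "from", "to", "pct_of_area"]]
    return ChangeSummary(
        total_area=total_area,
        net_change=net,
        percent_cover=cover,
        transition_areas=tidy,
        transition_percent=tidy_pct,
    )


def relative_interval_change(values: Sequence[float]) -> list[float]:
    """Relative change of a transition's area between consecutive intervals.

    For consecutive interval areas ``a, b`` the relative change is
    ``(a - b) / a * 100`` — positive when the flow declines.
    """
    values = list(values)
    out = []
    for a, b in zip(values, values[1:]):
        out.append((a - b) / a * 100.0 if a != 0 else float("nan"))
    return out


def cover_point_change(percent_cover: Sequence[float]) -> list[float]:
    """Successive differences of percent cover, in percentage points."""
    pct = list(percent_cover)
    return [b - a for a, b in zip(pct, pct[1:])]
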