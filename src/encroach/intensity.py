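"""Three-level Intensity Analysis of land-cover transition matrices.

Intensity Analysis compares observed annual change intensities to the
uniform intensities that would occur if change were spread evenly, at three
nested levels:

* **Interval**: how fast does the whole landscape change in each interval?
  ``S_t = change_t / (duration_t * A) * 100`` versus the extent-wide uniform
  rate ``U = sum(change_t) / (sum(duration_t) * A) * 100``.
* **Category**: which classes gain or lose actively?  Annual gain intensity
  ``G_tj`` is the class's annual gain relative to its size at the end of the
  interval; annual loss intensity ``L_ti`` relative to its size at the start.
  A class is *active* when the intensity exceeds ``U``, else *dormant*.
* **Transition**: which flows are targeted?  The annual transition intensity
  from class *i* onto gaining class *n*, ``R_tin``, is compared to the
  uniform gain intensity ``W_tn`` that the gain of *n* would have if drawn
  evenly from all non-*n* area at the start of the interval.  ``R > W``
  means *n* targets *i*; ``R < W`` means it avoids *i*.  The loss-side
  analogues ``Q_tmj`` (intensity of the flow from losing class *m* into *j*,
  relative to *j*'s final size) and ``V_tm`` follow the same framework.

Undefined intensities (zero denominators, e.g. a class absent at one date)
are reported as missing values and excluded from flags — never coerced to 0.
Percentages are carried at full precision; rounding is left to reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .change import TransitionMatrix
from .grids import InvalidInputError

__all__ = [
    "IntervalIntensity",
    "CategoryIntensity",
    "TransitionIntensity",
    "interval_level",
    "category_level",
    "transition_level",
    "loss_side_transition_level",
    "stationarity",
]


@dataclass(frozen=True)
class IntervalIntensity:
    """Interval-level results: annual change intensity per interval vs uniform."""

    s_t: pd.Series                 # % of landscape per year, one entry per interval
    u: float                       # uniform annual change, % per year
    total_change_pct: pd.Series    # per-interval change as % of landscape (S_t * duration)
    fast: pd.Series                # S_t > U
    durations: tuple[float, ...]


@dataclass(frozen=True)
class CategoryIntensity:
    """Category-level results for one interval."""

    gain_intensity: pd.Series      # G_tj, % per year (NaN when undefined)
    loss_intensity: pd.Series      # L_ti, % per year
    active_gainer: pd.Series      # boolean (pd.NA when intensity undefined)
    active_loser: pd.Series
    u: float


@dataclass(frozen=True)
class TransitionIntensity:
    """Transition-level results for one interval and one focal class.

    For the gain side, ``intensity`` holds ``R_tin`` per source class and
    ``uniform`` holds ``W_tn``; for the loss side, ``Q_tmj`` per destination
    class and ``V_tm``.  ``targets`` / ``avoids`` compare intensity with the
    uniform line.
    """

    focal: str
    side: str                      # "gain" or "loss"
    intensity: pd.Series
    uniform: float
    targets: pd.Series
    avoids: pd.Series


def _flags(intensity: pd.Series, threshold: float) -> pd.Series:
    flags = pd.Series(pd.NA, index=intensity.index, dtype="boolean")
    defined = intensity.notna()
    flags[defined] = intensity[defined] > threshold
    return flags


def interval_level(
    matrices: Sequence[TransitionMatrix],
    total_area: float | None = None,
    labels: Sequence[str] | None = None,
) -> IntervalIntensity:
    """Annual change intensity per interval and the extent-wide uniform rate.

    ``total_area`` defaults to the mean of the matrices' own totals, in which
    case the matrices must agree on total area within 0.5%; passing an
    explicit ``total_area`` overrides that consistency requirement (useful
    when matrices reconstructed from rounded published tables disagree with
    the year marginals).
    """
    if not matrices:
        raise InvalidInputError("at least one transition matrix is required")
    totals = np.array([m.total_area for m in matrices])
    if total_area is None and totals.max() - totals.min() > 0.005 * totals.mean():
        raise InvalidInputError("matrices disagree on total area by more than 0.5%")
    area = float(total_area) if total_area is not None else float(totals.mean())
    labels = list(labels) if labels is not None else list(range(len(matrices)))
    durations = tuple(m.duration for m in matrices)
    changes = np.array([m.change_area for m in matrices])
    s_t = pd.Series(changes / (np.array(durations) * area) * 100.0, index=labels)
    u = float(changes.sum() / (sum(durations) * area) * 100.0)
    return IntervalIntensity(
        s_t=s_t,
        u=u,
        total_change_pct=s_t * pd.Series(durations, index=labels),
        fast=s_t > u,
        durations=durations,
    )


def category_level(matrix: TransitionMatrix, u: float) -> CategoryIntensity:
    """Annual gain/loss intensity per category, flagged against the uniform rate.

    ``G_tj`` divides the annual gain of class *j* by its area at the end of
    the interval; ``L_ti`` divides the annual loss of class *i* by its area
    at the start.  A class with zero area in the relevant denominator has an
    undefined intensity (NaN) and no flag.
    """
    names = list(matrix.scheme.names)
    d = matrix.duration
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(matrix.col_totals > 0, (matrix.gains / d) / matrix.col_totals * 100.0, np.nan)
        l = np.where(matrix.row_totals > 0, (matrix.losses / d) / matrix.row_totals * 100.0, np.nan)
    gain = pd.Series(g, index=names)
    loss = pd.Series(l, index=names)
    return CategoryIntensity(
        gain_intensity=gain,
        loss_intensity=loss,
        active_gainer=_flags(gain, u),
        active_loser=_flags(loss, u),
        u=u,
    )


def transition_level(matrix: TransitionMatrix, gaining: int | str) -> TransitionIntensity:
    """Gain-side transition intensities onto the gaining class ``n``.

    ``R_tin`` is the annual flow from *i* into *n* relative to the size of
    *i* at the start of the interval; the uniform line ``W_tn`` spreads the
    annual gain of *n* over all non-*n* area at the start.
    """
    scheme = matrix.scheme
    n = scheme.index_of(gaining) if not isinstance(gaining, str) else scheme.names.index(gaining)
    names = list(scheme.names)
    d = matrix.duration
    area_t = matrix.row_totals
    sources = [i for i in range(scheme.J) if i != n]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.array(
            [
                (matrix.entries[i, n] / d) / area_t[i] * 100.0 if area_t[i] > 0 else np.nan
                for i in sources
            ]
        )
    denom = matrix.total_area - area_t[n]
    gain_n = matrix.gains[n]
    w = float((gain_n / d) / denom * 100.0) if denom > 0 else float("nan")
    intensity = pd.Series(r, index=[names[i] for i in sources])
    return TransitionIntensity(
        focal=names[n],
        side="gain",
        intensity=intensity,
        uniform=w,
        targets=_flags(intensity, w),
        avoids=_flags(-intensity, -w),
    )


def loss_side_transition_level(matrix: TransitionMatrix, losing: int | str) -> TransitionIntensity:
    """Loss-side transition intensities out of the losing class ``m``.

    ``Q_tmj`` is the annual flow from *m* into *j* relative to the size of
    *j* at the end of the interval; the uniform line ``V_tm`` spreads the
    annual loss of *m* over all non-*m* area at the end.
    """
    scheme = matrix.scheme
    m = scheme.index_of(losing) if not isinstance(losing, str) else scheme.names.index(losing)
    names = list(scheme.names)
    d = matrix.duration
    area_t1 = matrix.col_totals
    dests = [j for j in range(scheme.J) if j != m]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.array(
            [
                (matrix.entries[m, j] / d) / area_t1[j] * 100.0 if area_t1[j] > 0 else np.nan
                for j in dests
            ]
        )
    denom = matrix.total_area - area_t1[m]
    loss_m = matrix.losses[m]
    v = float((loss_m / d) / denom * 100.0) if denom > 0 else float("nan")
    intensity = pd.Series(q, index=[names[j] for j in dests])
    return TransitionIntensity(
        focal=names[m],
        side="loss",
        intensity=intensity,
        uniform=v,
        targets=_flags(intensity, v),
        avoids=_flags(-intensity, -v),
    )


def stationarity(flag_series: Sequence[pd.Series]) -> pd.DataFrame:
    """Cross-interval stationarity of intensity flags.

    A flag is *stationary* iff it is defined and identical across all
    intervals.  Returns one row per index entry with the shared value (where
    stationary) and the stationarity boolean.
    """
    if len(flag_series) < 2:
        raise InvalidInputError("stationarity needs flags from at least two intervals")
    frame = pd.concat(list(flag_series), axis=1)
    defined = frame.notna().all(axis=1)
    all_true = frame.fillna(False).all(axis=1)
    none_true = (~frame.fillna(True)).all(axis=1)
    stationary = defined & (all_true | none_true)
    value = pd.Series(pd.NA, index=frame.index, dtype="boolean")
    value[stationary] = all_true[stationary]
    return pd.DataFrame({"stationary": stationary, "value": value})
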