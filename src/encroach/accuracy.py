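"""Map-comparison metrics: confusion matrix, kappa and disagreement components.

Alongside overall, producer's and user's accuracy, the module decomposes
total disagreement ``D = 1 - sum_g p_gg`` into *quantity* disagreement
``Q = 0.5 * sum_g |p_g. - p_.g|`` (mismatched class proportions) and
*allocation* disagreement ``A = D - Q`` (misplaced but quantity-balanced
cells), on the proportion matrix ``p = counts / total``.  The two components
always satisfy ``Q + A = 1 - overall accuracy``.

The combined QADI index is taken as the Euclidean norm ``sqrt(Q**2 + A**2)``
of the two components — a 0-1 score whose (Q, A) coordinates are also the
point plotted on a QADI graph.  The combining rule is isolated in
:func:`qadi_index` so it can be swapped.

Dialect: confusion-matrix rows are the reference class, columns the mapped
class, for all I/O in this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import AlignmentError, ClassScheme, EmptyResultError, InvalidInputError, LandCoverMap

__all__ = [
    "ConfusionMatrix",
    "build_confusion",
    "accuracy_metrics",
    "disagreement",
    "qadi_index",
]


@dataclass(frozen=True, eq=False)
class ConfusionMatrix:
    """Reference-vs-map count table; rows = reference, columns = mapped."""

    counts: np.ndarray
    scheme: ClassScheme

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        J = self.scheme.J
        if counts.shape != (J, J):
            raise InvalidInputError(f"counts must be {J}x{J}, got {counts.shape}")
        if np.any(counts < 0):
            raise InvalidInputError("confusion counts must be non-negative")
        if counts.sum() <= 0:
            raise EmptyResultError("confusion matrix is empty")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        names = list(self.scheme.names)
        return pd.DataFrame(self.counts, index=names, columns=names)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path)
        return path

    @classmethod
    def read_csv(cls, path: str | Path, scheme: ClassScheme | None = None) -> "ConfusionMatrix":
        frame = pd.read_csv(path, index_col=0)
        if scheme is None:
            names = tuple(str(n) for n in frame.index)
            scheme = ClassScheme(codes=tuple(range(1, len(names) + 1)), names=names)
        return cls(counts=frame.to_numpy(), scheme=scheme)


def build_confusion(
    reference: LandCoverMap | Sequence[tuple[int, int]],
    mapped: LandCoverMap,
) -> ConfusionMatrix:
    """Tally a confusion matrix from an aligned reference map or labelled points.

    ``reference`` is either a map aligned with ``mapped``, or a sequence of
    ``(row, col, code)`` labelled points falling inside the map.  Nodata cells
    are excluded.
    """
    scheme = mapped.scheme
    code_to_idx = {code: k for k, code in enumerate(scheme.codes)}
    counts = np.zeros((scheme.J, scheme.J), dtype=np.int64)
    if isinstance(reference, LandCoverMap):
        if not reference.grid.aligned(mapped.grid):
            raise AlignmentError("reference and mapped grids are not aligned")
        valid = reference.grid.valid_mask & mapped.grid.valid_mask
        if not valid.any():
            raise EmptyResultError("no jointly valid cells")
        lookup = np.vectorize(code_to_idx.get, otypes=[np.int64])
        ia = lookup(reference.grid.values[valid])
        ib = lookup(mapped.grid.values[valid])
        np.add.at(counts, (ia, ib), 1)
    else:
        points = list(reference)
        if not points:
            raise EmptyResultError("no reference points")
        valid = mapped.grid.valid_mask
        for r, c, code in points:
            if not (0 <= r < mapped.grid.rows and 0 <= c < mapped.grid.cols):
                raise InvalidInputError(f"point ({r}, {c}) falls outside the map")
            if valid[r, c]:
                counts[code_to_idx[int(code)], code_to_idx[int(mapped.grid.values[r, c])]] += 1
        if counts.sum() == 0:
            raise EmptyResultError("all reference points fall on nodata")
    return ConfusionMatrix(counts=counts, scheme=scheme)


def accuracy_metrics(cm: ConfusionMatrix) -> dict:
    """Overall, per-class producer's/user's accuracy, error rates and kappa.

    Producer's accuracy for class *g* is ``diagonal / row sum`` (1 minus the
    omission error); user's accuracy is ``diagonal / column sum`` (1 minus
    the commission error).  Kappa compares observed agreement ``p_o`` with
    the chance agreement ``p_e`` from the marginal products.  Metrics with a
    zero denominator come back as NaN for that class.
    """
    p = cm.proportions
    diag = np.diag(p)
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        producers = np.where(rows > 0, diag / rows, np.nan)
        users = np.where(cols > 0, diag / cols, np.nan)
    p_o = float(diag.sum())
    p_e = float((rows * cols).sum())
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    names = list(cm.scheme.names)
    return {
        "overall_accuracy": p_o,
        "kappa": float(kappa),
        "producers_accuracy": dict(zip(names, producers.tolist())),
        "users_accuracy": dict(zip(names, users.tolist())),
        "omission_error": dict(zip(names, (1.0 - producers).tolist())),
        "commission_error": dict(zip(names, (1.0 - users).tolist())),
        "n": cm.total,
    }


def qadi_index(q: float, a: float) -> float:
    """Combine quantity and allocation disagreement into one 0-1 index.

    Uses the Euclidean norm of the (Q, A) point; swap this function to use a
    different combining rule.
    """
    return float(np.hypot(q, a))


def disagreement(cm: ConfusionMatrix) -> dict:
    """Quantity/allocation decomposition of map disagreement plus the QADI index.

    Returns ``Q``, ``A``, total disagreement ``D``, the combined ``QADI`` and
    the ``(Q, A)`` plot coordinates; all components lie in [0, 1] and satisfy
    ``Q + A = D = 1 - overall accuracy``.
    """
    p = cm.proportions
    d = 1.0 - float(np.diag(p).sum())
    q = 0.5 * float(np.abs(p.sum(axis=1) - p.sum(axis=0)).sum())
    a = d - q
    a = max(a, 0.0)  # guard tiny negative round-off
    return {"Q": q, "A": a, "D": d, "QADI": qadi_index(q, a), "plot_xy": (q, a)}
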