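"""CA-Markov simulation of future land cover.

The simulation follows the six phases of a MOLUSCE-style workflow: inputs
(maps + covariates), covariate correlation screening, Markov area change,
MLP transition-potential modelling, cellular-automata allocation, and
validation against a held-out map.

The division of labour is the classic CA-Markov split: the Markov chain
estimated from one observed interval decides *how much* area moves between
classes per step, while per-cell transition potentials — a multilayer
perceptron over standardized terrain covariates, the current class and the
Moore-neighbourhood class composition — decide *where* it moves.  Allocation
converts the highest-scoring source cells first, with the neighbourhood
weight ``w`` boosting cells adjacent to existing destination-class patches.

Defaults follow the MOLUSCE convention: one hidden layer of 10 logistic
units, SGD with learning rate 0.1 and momentum 0.05, at most 1000 epochs,
and a balanced seeded sample of change/persistence cells.  The whole
simulate path is a pure function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

from . import accuracy as accuracy_mod
from .change import TransitionMatrix
from .grids import AlignmentError, ClassScheme, EmptyResultError, Grid, InvalidInputError, LandCoverMap
from .synthetic import CovariateStack, moore_fraction

__all__ = [
    "MLPHyperparams",
    "TransitionPotentialModel",
    "SimulationConfig",
    "DegenerateModelError",
    "AllocationError",
    "covariate_correlation",
    "markov_project",
    "fit_transition_potential",
    "ca_allocate",
    "simulate",
    "validate",
    "persistence_baseline",
]


class DegenerateModelError(InvalidInputError):
    """The training data carry no usable signal (no valid cells)."""


class AllocationError(InvalidInputError):
    """A transition's demand exceeds the available source cells."""


def covariate_correlation(stack: CovariateStack, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation between covariates over jointly valid cells.

    A constant covariate has undefined correlations (NaN off-diagonal); the
    diagonal is 1 by convention.
    """
    names = list(names or stack.names)
    if len(names) < 2:
        raise InvalidInputError("correlation needs at least two covariates")
    mask = stack.valid_mask()
    table = pd.DataFrame({n: stack[n].values.astype(float)[mask] for n in names})
    corr = table.corr(method="pearson")
    np.fill_diagonal(corr.to_numpy(), 1.0)  # keep the diagonal defined even for constants
    for n in names:
        if table[n].std() == 0:
            corr.loc[n, corr.columns != n] = np.nan
            corr.loc[corr.index != n, n] = np.nan
            corr.loc[n, n] = 1.0
    return corr


def markov_project(
    matrix: TransitionMatrix, areas_t: Sequence[float], steps: int
) -> pd.DataFrame:
    """Project class areas ``steps`` intervals ahead with the row-normalized chain.

    ``P`` is the transition matrix normalized by row; a zero-area class row is
    treated as identity (the class persists).  Total area is conserved at
    every step.  Returns one row per step (step 1 .. steps) plus step 0.
    """
    if steps < 1:
        raise InvalidInputError("steps must be >= 1")
    areas = np.asarray(areas_t, dtype=float)
    row_sums = matrix.row_totals
    P = np.eye(matrix.scheme.J)
    nonzero = row_sums > 0
    P[nonzero] = matrix.entries[nonzero] / row_sums[nonzero, None]
    out = [areas]
    for _ in range(steps):
        out.append(out[-1] @ P)
    return pd.DataFrame(out, columns=list(matrix.scheme.names), index=range(steps + 1))


@dataclass(frozen=True)
class MLPHyperparams:
    """MOLUSCE-style multilayer-perceptron training settings."""

    hidden: int = 10
    learning_rate: float = 0.1
    momentum: float = 0.05
    max_epochs: int = 1000
    max_per_class: int = 5000      # cap on the balanced per-destination sample
    min_samples: int = 50          # below this a transition falls back to its base rate


def _feature_table(
    codes: np.ndarray, stack: CovariateStack, scheme: ClassScheme
) -> tuple[np.ndarray, list[str]]:
    """Per-cell features: standardized covariates + class one-hot + Moore fractions."""
    fields, _ = stack.standardize()
    columns = [fields[n].ravel() for n in stack.names]
    names = list(stack.names)
    for code, name in zip(scheme.codes, scheme.names):
        columns.append((codes == code).astype(float).ravel())
        names.append(f"is:{name}")
    for code, name in zip(scheme.codes, scheme.names):
        columns.append(moore_fraction(codes, code).ravel())
        names.append(f"moore:{name}")
    return np.column_stack(columns), names


@dataclass(frozen=True, eq=False)
class TransitionPotentialModel:
    """Fitted per-transition suitability scorer.

    One binary MLP per modelled transition (cells of the source class that
    changed to the destination vs those that did not) maps a cell's feature
    vector to a potential in [0, 1].  Transitions observed fewer than
    ``min_samples`` times fall back to their empirical base rate (zero when
    unobserved).  Training is balanced, so potentials are ranking scores,
    not calibrated probabilities — the Markov chain owns the quantities.
    The same seed and data reproduce the model exactly.
    """

    scheme: ClassScheme
    stack_names: tuple[str, ...]
    classifiers: Mapping[tuple[int, int], MLPClassifier]
    base_rates: Mapping[tuple[int, int], float]
    hyperparams: MLPHyperparams
    seed: int
    training_accuracy: Mapping[tuple[int, int], float]

    def potentials(
        self, current: LandCoverMap, stack: CovariateStack
    ) -> dict[tuple[int, int], Grid]:
        """Per-transition potential grids for the current map state.

        Cells outside the transition's source class score 0.
        """
        codes = current.grid.values
        features, _ = _feature_table(codes, stack, self.scheme)
        template = current.grid
        out: dict[tuple[int, int], Grid] = {}
        for (i, j), rate in self.base_rates.items():
            clf = self.classifiers.get((i, j))
            if clf is not None:
                positive = list(clf.classes_).index(1)
                values = clf.predict_proba(features)[:, positive].reshape(codes.shape)
            else:
                values = np.full(codes.shape, rate)
            values = np.where(codes == i, values, 0.0)
            out[(i, j)] = template.with_values(values, kind="continuous", nodata=None)
        return out


def fit_transition_potential(
    map_t: LandCoverMap,
    map_t1: LandCoverMap,
    stack: CovariateStack,
    seed: int = 0,
    hyperparams: MLPHyperparams | None = None,
) -> TransitionPotentialModel:
    """Train the transition-potential model on one observed interval.

    Observations are (features at t -> changed-to-class at t+1) over jointly
    valid cells.  For each transition ``i -> j`` with at least ``min_samples``
    observed change cells, a seeded balanced sample (changed vs unchanged
    source cells, capped at ``max_per_class`` per side) trains a binary MLP;
    sparser transitions fall back to their empirical base rate.
    """
    hp = hyperparams or MLPHyperparams()
    if not (map_t.grid.aligned(map_t1.grid) and map_t.grid.aligned(stack.template)):
        raise AlignmentError("maps and covariates are not aligned")
    scheme = map_t.scheme
    codes_t = map_t.grid.values
    codes_t1 = map_t1.grid.values
    valid = map_t.grid.valid_mask & map_t1.grid.valid_mask & stack.valid_mask()
    if not valid.any():
        raise DegenerateModelError("no valid training cells")
    features, _ = _feature_table(codes_t, stack, scheme)
    flat_valid = valid.ravel()
    flat_t = codes_t.ravel()
    flat_t1 = codes_t1.ravel()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 3)))
    classifiers: dict[tuple[int, int], MLPClassifier] = {}
    base_rates: dict[tuple[int, int], float] = {}
    training_accuracy: dict[tuple[int, int], float] = {}
    for i in scheme.codes:
        cells = flat_valid & (flat_t == i)
        n_source = int(cells.sum())
        for j in scheme.codes:
            if i == j:
                continue
            changed = cells & (flat_t1 == j)
            n_ij = int(changed.sum())
            base_rates[(i, j)] = n_ij / n_source if n_source else 0.0
            n_other = n_source - n_ij
            if n_ij < hp.min_samples or n_other < hp.min_samples:
                continue  # too sparse to model; empirical base rate stands in
            n_per_side = min(n_ij, n_other, hp.max_per_class)
            pos = rng.choice(np.flatnonzero(changed), size=n_per_side, replace=False)
            neg = rng.choice(np.flatnonzero(cells & ~changed), size=n_per_side, replace=False)
            idx = np.concatenate([pos, neg])
            X = features[idx]
            y = np.concatenate([np.ones(n_per_side, int), np.zeros(n_per_side, int)])
            clf = MLPClassifier(
                hidden_layer_sizes=(hp.hidden,),
                activation="logistic",
                solver="sgd",
                learning_rate_init=hp.learning_rate,
                momentum=hp.momentum,
                max_iter=hp.max_epochs,
                random_state=int(
                    np.random.SeedSequence((int(seed), 4, int(i), int(j))).generate_state(1)[0]
                    % (2**31)
                ),
                n_iter_no_change=10,
            )
            clf.fit(X, y)
            classifiers[(int(i), int(j))] = clf
            training_accuracy[(int(i), int(j))] = float(clf.score(X, y))
    return TransitionPotentialModel(
        scheme=scheme,
        stack_names=tuple(stack.names),
        classifiers=classifiers,
        base_rates=base_rates,
        hyperparams=hp,
        seed=int(seed),
        training_accuracy=training_accuracy,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """CA simulation settings: projection steps, neighbourhood weight, seed."""

    steps: int = 1
    neighborhood_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise InvalidInputError("steps must be >= 1")
        if self.neighborhood_weight < 0:
            raise InvalidInputError("neighborhood weight must be >= 0")


def _largest_remainder(fractional: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative fractional counts to integers preserving their sum."""
    floors = np.floor(fractional).astype(int)
    deficit = int(total - floors.sum())
    if deficit > 0:
        order = np.argsort(-(fractional - floors), kind="stable")
        floors[order[:deficit]] += 1
    return floors


def ca_allocate(
    current: LandCoverMap,
    potentials: Mapping[tuple[int, int], Grid],
    targets: Mapping[tuple[int, int], int],
    w: float = 1.0,
    seed: int = 0,
) -> LandCoverMap:
    """Convert, per transition, the highest-scoring source cells to meet targets.

    Cell score = potential x (Moore fraction of destination class) ** w, with
    ``w = 0`` disabling the neighbourhood term.  Ties are broken by a seeded
    shuffle; realized counts equal the targets exactly; all other cells
    persist.  Demands above the available source cells raise
    :class:`AllocationError`.
    """
    codes = current.grid.values.copy()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 5)))
    tiebreak = rng.permutation(codes.size).reshape(codes.shape)
    claimed = np.zeros(codes.shape, dtype=bool)
    for (i, j), demand in sorted(targets.items()):
        demand = int(demand)
        if demand == 0:
            continue
        pot = potentials[(i, j)].values
        if w == 0:
            score = pot.astype(float)
        else:
            score = pot * moore_fraction(current.grid.values, j) ** w
        eligible = (current.grid.values == i) & current.grid.valid_mask & ~claimed
        n_eligible = int(eligible.sum())
        if demand > n_eligible:
            raise AllocationError(
                f"transition {i}->{j} demands {demand} cells but only {n_eligible} are available"
            )
        flat = np.flatnonzero(eligible.ravel())
        order = np.lexsort((tiebreak.ravel()[flat], -score.ravel()[flat]))
        chosen = flat[order[:demand]]
        r, c = np.unravel_index(chosen, codes.shape)
        codes[r, c] = j
        claimed[r, c] = True
    return LandCoverMap(grid=current.grid.with_values(codes), scheme=current.scheme)


def simulate(
    start: LandCoverMap,
    model: TransitionPotentialModel,
    stack: CovariateStack,
    matrix: TransitionMatrix,
    config: SimulationConfig,
) -> list[LandCoverMap]:
    """Iterate Markov projection -> potentials -> CA allocation per step.

    Per step, the Markov chain estimated from ``matrix`` converts the current
    class composition into per-transition cell demands (largest-remainder
    rounding keeps row sums exact), potentials are re-evaluated on the
    evolving map, and allocation converts cells.  Output is one map per step;
    class areas match the Markov projection within one pixel per class.
    """
    scheme = start.scheme
    row_sums = matrix.row_totals
    P = np.eye(scheme.J)
    nonzero = row_sums > 0
    P[nonzero] = matrix.entries[nonzero] / row_sums[nonzero, None]
    out: list[LandCoverMap] = []
    current = start
    for step in range(config.steps):
        counts = np.array(
            [np.count_nonzero(current.grid.values[current.grid.valid_mask] == code) for code in scheme.codes]
        )
        targets: dict[tuple[int, int], int] = {}
        for a, code_i in enumerate(scheme.codes):
            expected = counts[a] * P[a]
            cells = _largest_remainder(expected, counts[a])
            for b, code_j in enumerate(scheme.codes):
                if a != b and cells[b] > 0:
                    targets[(code_i, code_j)] = int(cells[b])
        potentials = model.potentials(current, stack)
        for key in targets:
            if key not in potentials:
                potentials[key] = current.grid.with_values(
                    np.zeros(current.grid.shape), kind="continuous", nodata=None
                )
        current = ca_allocate(
            current,
            potentials,
            targets,
            w=config.neighborhood_weight,
            seed=int(np.random.SeedSequence((int(config.seed), 6, step)).generate_state(1)[0] % (2**31)),
        )
        out.append(current)
    return out


def validate(simulated: LandCoverMap, reference: LandCoverMap) -> dict:
    """Overall % correct, kappa and the QADI decomposition of a simulated map."""
    cm = accuracy_mod.build_confusion(reference, simulated)
    metrics = accuracy_mod.accuracy_metrics(cm)
    dis = accuracy_mod.disagreement(cm)
    return {
        "overall_percent_correct": metrics["overall_accuracy"] * 100.0,
        "kappa": metrics["kappa"],
        "Q": dis["Q"],
        "A": dis["A"],
        "QADI": dis["QADI"],
        "n": metrics["n"],
    }


def persistence_baseline(start: LandCoverMap, reference: LandCoverMap) -> dict:
    """Validation metrics of the no-change (all-persistence) map.

    The floor any useful transition model must beat: predict that nothing
    changes and score the start map against the reference.
    """
    return validate(start, reference)
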