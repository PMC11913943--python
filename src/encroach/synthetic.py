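"""Synthetic landscape generator.

The study site this pipeline emulates is a ~350 ha grassland reserve observed
at four dates, where woody vegetation expands into grassland modulated by
terrain and by the woody fraction of each cell's Moore neighbourhood.  No
imagery is redistributed with the package, so this module generates covariate
stacks and multi-date land-cover series with *known* transition dynamics:
every downstream stage (cross-tabulation, Intensity Analysis, CA-Markov
fitting) can then be tested against ground truth.

Latent surfaces are seeded Gaussian white noise smoothed with a uniform
kernel — a cheap, dependency-free stand-in for a Gaussian random field with a
tunable correlation length.  Cell transitions follow a logistic rule

    P(i -> j) = expit(base_logit + coef . x_std + neighbor_coef * f_j)

where ``x_std`` are the standardized covariates and ``f_j`` is the fraction
of the destination class among the 8 Moore neighbours.  The standardization
constants are stored with the series so recovery tests can compare fitted
against true coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit
from shapely.geometry import LineString

from .grids import (
    ClassScheme,
    Grid,
    InvalidInputError,
    LandCoverMap,
    derive_aspect,
    derive_slope,
    derive_twi,
    distance_from_lines,
    write_grid,
)

__all__ = [
    "LandscapeParams",
    "DynamicsParams",
    "TransitionRule",
    "CovariateStack",
    "SeriesResult",
    "generate_covariates",
    "generate_initial_landcover",
    "simulate_series",
    "moore_fraction",
    "bisley_scheme",
    "bisley_like_params",
    "bisley_like_dynamics",
    "write_series",
]

COVARIATE_NAMES = ("dem", "slope", "aspect", "twi", "road_dist")


def bisley_scheme() -> ClassScheme:
    """Three-class scheme: woody vegetation (1), grasses (2), bare areas (3)."""
    return ClassScheme(codes=(1, 2, 3), names=("woody vegetation", "grasses", "bare areas"))


@dataclass(frozen=True)
class LandscapeParams:
    """Static landscape properties.

    Defaults mimic the emulated reserve: 374x374 cells at 5 m (~350 ha),
    elevation between 720 and 840 m, and 2009-like class fractions.
    """

    shape: tuple[int, int] = (374, 374)
    pixel_size: float = 5.0
    dem_range: tuple[float, float] = (720.0, 840.0)
    smoothness: int = 15
    class_fractions: tuple[float, float, float] = (0.3769, 0.6025, 0.0206)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dem_range[0] < self.dem_range[1]:
            raise InvalidInputError("dem_range must satisfy min < max")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise InvalidInputError("class_fractions must sum to 1")


@dataclass(frozen=True)
class TransitionRule:
    """Logistic per-interval transition rule for one ordered class pair."""

    base_logit: float
    covariate_coefs: Mapping[str, float] = field(default_factory=dict)
    neighbor_coef: float = 0.0


@dataclass(frozen=True)
class DynamicsParams:
    """Transition dynamics: one logistic rule per modelled (source, dest) pair."""

    rules: Mapping[tuple[int, int], TransitionRule]
    n_steps: int = 3
    durations: tuple[float, ...] = (5.0, 5.0, 4.0)

    def __post_init__(self) -> None:
        if len(self.durations) != self.n_steps:
            raise InvalidInputError("durations must have one entry per step")
        if any(d <= 0 for d in self.durations):
            raise InvalidInputError("durations must all be > 0")


def bisley_like_dynamics() -> DynamicsParams:
    """Encroachment dynamics with realistic per-interval magnitudes.

    Per-interval base rates are set to the order observed in the emulated
    reserve (grass->woody ~0.25 per 5-year interval, small grass->bare and
    woody->grass flows, bare mostly reverting to grass).  Every flow is
    spatially structured, as the underlying processes are: encroachment
    carries a strong negative elevation coefficient and positive wetness and
    woody-neighbourhood coefficients (it climbs up from wet, low-lying ground
    and spreads from thicket edges); reversion to grass favours high, dry
    ground at grass edges; bare patches open near roads (disturbance proxy)
    and revegetate from adjacent grass.
    """
    return DynamicsParams(
        rules={
            (2, 1): TransitionRule(-1.2, {"dem": -1.5, "twi": 0.5}, neighbor_coef=2.0),
            (1, 2): TransitionRule(-3.6, {"dem": 1.0}, neighbor_coef=1.5),
            (2, 3): TransitionRule(-3.4, {"road_dist": -1.0}, neighbor_coef=1.0),
            (3, 2): TransitionRule(0.4, neighbor_coef=1.0),
        },
        n_steps=3,
        durations=(5.0, 5.0, 4.0),
    )


@dataclass(frozen=True, eq=False)
class CovariateStack:
    """Aligned continuous covariate grids on one lattice."""

    grids: Mapping[str, Grid]
    road: LineString | None = None

    def __post_init__(self) -> None:
        grids = dict(self.grids)
        ref = next(iter(grids.values()))
        for name, g in grids.items():
            if not g.aligned(ref):
                raise InvalidInputError(f"covariate {name!r} is not aligned with the stack")
        object.__setattr__(self, "grids", grids)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.grids)

    @property
    def template(self) -> Grid:
        return next(iter(self.grids.values()))

    def __getitem__(self, name: str) -> Grid:
        return self.grids[name]

    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.template.shape, dtype=bool)
        for g in self.grids.values():
            mask &= g.valid_mask & np.isfinite(g.values.astype(float))
        return mask

    def standardize(self, names: Sequence[str] | None = None) -> tuple[dict[str, np.ndarray], dict[str, tuple[float, float]]]:
        """Standardized covariate arrays and their (mean, sd) constants.

        Statistics are computed over jointly valid cells; a constant covariate
        keeps sd 1 so it standardizes to zero rather than blowing up.
        """
        names = list(names or self.names)
        mask = self.valid_mask()
        fields: dict[str, np.ndarray] = {}
        constants: dict[str, tuple[float, float]] = {}
        for name in names:
            v = self.grids[name].values.astype(float)
            mu = float(np.mean(v[mask]))
            sd = float(np.std(v[mask]))
            if sd == 0:
                sd = 1.0
            fields[name] = np.where(mask, (v - mu) / sd, 0.0)
            constants[name] = (mu, sd)
        return fields, constants


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], smoothness: int) -> np.ndarray:
    noise = rng.standard_normal(shape)
    size = max(1, int(smoothness))
    if size > 1:
        noise = ndimage.uniform_filter(noise, size=size, mode="reflect")
    return noise


def _rescale(field_: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = field_.min(), field_.max()
    if fmax == fmin:
        return np.full_like(field_, (lo + hi) / 2)
    return lo + (field_ - fmin) * (hi - lo) / (fmax - fmin)


def _random_road(rng: np.random.Generator, params: LandscapeParams) -> LineString:
    """A polyline crossing the extent west to east through random waypoints."""
    rows, cols = params.shape
    width = cols * params.pixel_size
    height = rows * params.pixel_size
    n_way = 4
    xs = np.linspace(0.0, width, n_way + 2)
    ys = rng.uniform(0.1 * height, 0.9 * height, size=n_way + 2)
    return LineString(list(zip(xs, ys)))


def generate_covariates(params: LandscapeParams) -> CovariateStack:
    """Seeded covariate stack: DEM plus derived slope, aspect, TWI and road distance.

    The DEM is a smoothed random field rescaled exactly to ``dem_range``; the
    road is a seeded random polyline crossing the extent.  Deterministic under
    a fixed seed.
    """
    ss = np.random.SeedSequence(params.seed)
    dem_rng, road_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    origin = (0.0, params.shape[0] * params.pixel_size)
    dem_values = _rescale(
        _smooth_field(dem_rng, params.shape, params.smoothness),
        params.dem_range[0],
        params.dem_range[1],
    )
    dem = Grid(values=dem_values, pixel_size=params.pixel_size, origin=origin, kind="continuous")
    road = _random_road(road_rng, params)
    grids = {
        "dem": dem,
        "slope": derive_slope(dem),
        "aspect": derive_aspect(dem),
        "twi": derive_twi(dem),
        "road_dist": distance_from_lines(dem, road),
    }
    return CovariateStack(grids=grids, road=road)


def generate_initial_landcover(covariates: CovariateStack, params: LandscapeParams) -> LandCoverMap:
    """Initial map: a smoothed latent field thresholded at class-fraction quantiles.

    Classes come out spatially clustered (patches at the latent field's
    correlation length) with realized fractions matching ``class_fractions``
    up to quantile granularity; a zero-fraction class is simply absent.
    """
    ss = np.random.SeedSequence((params.seed, 1))
    latent = _smooth_field(np.random.default_rng(ss), params.shape, params.smoothness)
    scheme = bisley_scheme()
    cum = np.cumsum(params.class_fractions)
    thresholds = [np.quantile(latent, q) for q in cum[:-1]]
    codes = np.full(params.shape, scheme.codes[-1], dtype=np.int64)
    # Assign from the top of the cumulative ladder downward so earlier classes win.
    for code, thr in zip(scheme.codes[-2::-1], thresholds[::-1]):
        codes[latent <= thr] = code
    grid = covariates.template.with_values(codes, kind="categorical", nodata=None)
    return LandCoverMap(grid=grid, scheme=scheme)


def moore_fraction(codes: np.ndarray, code: int) -> np.ndarray:
    """Fraction of the 8 Moore neighbours equal to ``code`` (edge cells use
    their actual neighbour count)."""
    onehot = (codes == code).astype(float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    num = ndimage.convolve(onehot, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(onehot), kernel, mode="constant", cval=0.0)
    return num / den


@dataclass(frozen=True, eq=False)
class SeriesResult:
    """A simulated multi-date land-cover series with its generating context."""

    maps: tuple[LandCoverMap, ...]
    covariates: CovariateStack
    dynamics: DynamicsParams
    standardization: Mapping[str, tuple[float, float]]
    seed: int


def simulate_series(
    initial: LandCoverMap,
    covariates: CovariateStack,
    dyn: DynamicsParams,
    seed: int,
) -> SeriesResult:
    """Simulate ``dyn.n_steps`` intervals of logistic transition dynamics.

    Each cell of class *i* changes to class *j* with probability
    ``expit(base + coef . x_std + neighbor_coef * f_j)`` per interval,
    independently across cells given the neighbourhood state at the start of
    the interval.  If a cell's candidate transition probabilities sum above 1
    they are renormalized.  Output holds ``n_steps + 1`` maps, the first being
    the input.  Deterministic under a fixed seed.
    """
    if not initial.grid.aligned(covariates.template):
        raise InvalidInputError("initial map and covariates are not aligned")
    fields, constants = covariates.standardize()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 2)))
    maps = [initial]
    current = initial.grid.values.copy()
    by_source: dict[int, list[tuple[int, TransitionRule]]] = {}
    for (i, j), rule in sorted(dyn.rules.items()):
        by_source.setdefault(i, []).append((j, rule))
    for _ in range(dyn.n_steps):
        new = current.copy()
        u = rng.random(current.shape)
        for i, rules in by_source.items():
            cells = current == i
            if not cells.any():
                continue
            probs = []
            for j, rule in rules:
                logit = np.full(current.shape, rule.base_logit, dtype=float)
                for name, coef in rule.covariate_coefs.items():
                    logit += coef * fields[name]
                if rule.neighbor_coef:
                    logit += rule.neighbor_coef * moore_fraction(current, j)
                probs.append(expit(logit))
            total = np.sum(probs, axis=0)
            scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-300), 1.0)
            cum = np.zeros(current.shape)
            for (j, _), p in zip(rules, probs):
                lo = cum.copy()
                cum = cum + p * scale
                hit = cells & (u >= lo) & (u < cum)
                new[hit] = j
        current = new
        maps.append(
            LandCoverMap(grid=initial.grid.with_values(current.copy()), scheme=initial.scheme)
        )
    return SeriesResult(
        maps=tuple(maps),
        covariates=covariates,
        dynamics=dyn,
        standardization=constants,
        seed=int(seed),
    )


def bisley_like_params(seed: int = 0) -> LandscapeParams:
    return LandscapeParams(seed=seed)


def write_series(series: SeriesResult, outdir: str | Path) -> Path:
    """Write covariates and the map series as GeoTIFFs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, str] = {}
    for name, g in series.covariates.grids.items():
        path = outdir / f"covariate_{name}.tif"
        write_grid(g, path)
        inventory[f"covariate:{name}"] = path.name
    for k, m in enumerate(series.maps):
        path = outdir / f"landcover_t{k}.tif"
        write_grid(m.grid, path)
        inventory[f"landcover:t{k}"] = path.name
    scheme = series.maps[0].scheme
    manifest = {
        "seed": series.seed,
        "n_steps": series.dynamics.n_steps,
        "durations": list(series.dynamics.durations),
        "rules": {
            f"{i}->{j}": {
                "base_logit": r.base_logit,
                "covariate_coefs": dict(r.covariate_coefs),
                "neighbor_coef": r.neighbor_coef,
            }
            for (i, j), r in sorted(series.dynamics.rules.items())
        },
        "standardization": {k: list(v) for k, v in series.standardization.items()},
        "scheme": {"codes": list(scheme.codes), "names": list(scheme.names)},
        "inventory": inventory,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
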