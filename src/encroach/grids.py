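"""Raster grid model, I/O, resampling and terrain-covariate derivation.

This module provides the lattice data model shared by every stage of the
bush-encroachment pipeline: a single-band :class:`Grid` in a projected
coordinate system, a :class:`ClassScheme` naming the land-cover categories,
and the terrain derivatives used as drivers of woody expansion — slope,
aspect, topographic wetness index (TWI) and Euclidean distance from roads.

Conventions
-----------
* Grids are row-major with row 0 the northernmost row; the centre of cell
  ``(r, c)`` is at ``origin + ((c + 0.5) * pixel_size, -(r + 0.5) * pixel_size)``
  where ``origin`` is the map coordinate of the top-left corner.
* Two grids are *aligned* iff they share shape, pixel size and origin.
  All multi-grid operations require alignment.
* Slope and aspect use the Horn 3x3 kernel; aspect is measured in degrees
  clockwise from north toward the steepest downslope direction, with flat
  cells assigned the sentinel ``-1``.
* Flow routing for the TWI is D8 (steepest descent among the 8 neighbours)
  with deterministic tie-breaking in the fixed order N, NE, E, SE, S, SW,
  W, NW; pits accumulate without breaching.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import shape as _geojson_shape

__all__ = [
    "Grid",
    "ClassScheme",
    "LandCoverMap",
    "GridError",
    "GridFormatError",
    "UnsupportedInputError",
    "InvalidMethodError",
    "EmptyResultError",
    "InvalidInputError",
    "AlignmentError",
    "read_grid",
    "write_grid",
    "resample_to",
    "derive_slope",
    "derive_aspect",
    "derive_twi",
    "distance_from_lines",
    "read_lines_geojson",
    "FLAT_ASPECT",
]


class GridError(Exception):
    """Base class for raster errors."""


class GridFormatError(GridError):
    """File could not be parsed, or values violate the declared kind."""


class UnsupportedInputError(GridError):
    """Input is readable but not supported (e.g. multi-band raster)."""


class InvalidMethodError(GridError):
    """Requested resampling method is invalid for the grid kind."""


class EmptyResultError(GridError):
    """An operation would produce a result with no valid cells."""


class InvalidInputError(GridError):
    """Operation input is structurally invalid (e.g. empty line set)."""


class AlignmentError(GridError):
    """Grids participating in a multi-grid operation are not aligned."""


#: Aspect sentinel for flat cells (slope exactly zero).
FLAT_ASPECT = -1.0

# D8 neighbour offsets in the deterministic tie-break order N, NE, E, SE, S, SW, W, NW.
_D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


@dataclass(frozen=True, eq=False)
class Grid:
    """A single-band raster on a regular square lattice.

    Parameters
    ----------
    values
        2-D array; continuous floats or non-negative integer class codes.
    pixel_size
        Cell edge length in metres (> 0).
    origin
        Map coordinate ``(x, y)`` of the top-left *corner* of cell (0, 0).
    nodata
        Sentinel marking invalid cells, or ``None`` if every cell is valid.
    kind
        ``"categorical"`` or ``"continuous"``.
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float | int | None = None
    kind: Literal["categorical", "continuous"] = "continuous"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise GridFormatError(f"grid values must be 2-D and non-empty, got shape {values.shape}")
        if not (self.pixel_size > 0):
            raise GridFormatError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.kind not in ("categorical", "continuous"):
            raise GridFormatError(f"unknown grid kind {self.kind!r}")
        if self.kind == "categorical":
            valid = values[self._valid_mask_of(values)]
            if valid.size and not np.all(np.mod(valid, 1) == 0):
                raise GridFormatError("categorical grid contains non-integer class codes")
            if not np.issubdtype(values.dtype, np.integer):
                integral_nodata = self.nodata is None or (
                    np.isfinite(self.nodata) and float(self.nodata) == int(self.nodata)
                )
                if integral_nodata:
                    values = values.astype(np.int64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))
        object.__setattr__(self, "pixel_size", float(self.pixel_size))

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size ** 2 / 10_000.0

    def aligned(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.pixel_size, other.pixel_size, rel_tol=0, abs_tol=tol)
            and math.isclose(self.origin[0], other.origin[0], rel_tol=0, abs_tol=tol)
            and math.isclose(self.origin[1], other.origin[1], rel_tol=0, abs_tol=tol)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates ``(X, Y)`` of every cell centre, each shaped like the grid."""
        ox, oy = self.origin
        x = ox + (np.arange(self.cols) + 0.5) * self.pixel_size
        y = oy - (np.arange(self.rows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    # -- values -------------------------------------------------------------

    def _valid_mask_of(self, values: np.ndarray) -> np.ndarray:
        if self.nodata is None:
            return np.ones(values.shape, dtype=bool)
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            return ~np.isnan(values)
        return values != self.nodata

    @property
    def valid_mask(self) -> np.ndarray:
        return self._valid_mask_of(self.values)

    def with_values(
        self,
        values: np.ndarray,
        kind: Literal["categorical", "continuous"] | None = None,
        nodata: float | int | None | Literal["keep"] = "keep",
    ) -> "Grid":
        """A new grid on the same geometry with different values."""
        return Grid(
            values=values,
            pixel_size=self.pixel_size,
            origin=self.origin,
            nodata=self.nodata if nodata == "keep" else nodata,
            kind=kind or self.kind,
        )


@dataclass(frozen=True)
class ClassScheme:
    """Ordered land-cover categories; ``J`` is the number of categories."""

    codes: tuple[int, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = tuple(int(c) for c in self.codes)
        names = tuple(str(n) for n in self.names)
        if len(codes) != len(names):
            raise InvalidInputError("codes and names must have equal length")
        if len(set(codes)) != len(codes):
            raise InvalidInputError("class codes must be unique")
        if len(codes) < 2:
            raise InvalidInputError("a class scheme needs at least two categories")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "names", names)

    @property
    def J(self) -> int:
        return len(self.codes)

    def index_of(self, key: int | str) -> int:
        if isinstance(key, str):
            return self.names.index(key)
        return self.codes.index(int(key))

    def name_of(self, code: int) -> str:
        return self.names[self.codes.index(int(code))]


@dataclass(frozen=True, eq=False)
class LandCoverMap:
    """A categorical grid observed at one time point, with its class scheme."""

    grid: Grid
    scheme: ClassScheme

    def __post_init__(self) -> None:
        if self.grid.kind != "categorical":
            raise GridFormatError("a land-cover map requires a categorical grid")
        valid = self.grid.values[self.grid.valid_mask]
        unknown = set(np.unique(valid).tolist()) - set(self.scheme.codes)
        if unknown:
            raise GridFormatError(f"land-cover map contains undeclared class codes {sorted(unknown)}")

    def counts(self) -> dict[str, int]:
        """Valid-cell count per class name."""
        valid = self.grid.values[self.grid.valid_mask]
        return {
            name: int(np.count_nonzero(valid == code))
            for code, name in zip(self.scheme.codes, self.scheme.names)
        }

    def areas_ha(self) -> dict[str, float]:
        pa = self.grid.pixel_area_ha
        return {name: n * pa for name, n in self.counts().items()}

    def fractions(self) -> dict[str, float]:
        counts = self.counts()
        total = sum(counts.values())
        return {name: (n / total if total else float("nan")) for name, n in counts.items()}


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid and single-band GeoTIFF
# ---------------------------------------------------------------------------

_ASCII_SUFFIXES = {".asc", ".agr", ".txt"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_grid(path: str | Path, kind: Literal["categorical", "continuous"]) -> Grid:
    """Read a single-band raster (GeoTIFF or ESRI ASCII grid).

    Categorical values are cast to integer codes; a categorical file holding
    fractional values raises :class:`GridFormatError`.  Multi-band rasters
    raise :class:`UnsupportedInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"no such raster: {path}")
    suffix = path.suffix.lower()
    if suffix in _ASCII_SUFFIXES:
        return _read_ascii(path, kind)
    if suffix in _TIFF_SUFFIXES:
        return _read_geotiff(path, kind)
    raise GridFormatError(f"unsupported raster format {suffix!r} (use .tif/.tiff or .asc)")


def write_grid(grid: Grid, path: str | Path) -> Path:
    """Write a grid as GeoTIFF or ESRI ASCII, chosen by file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _ASCII_SUFFIXES:
        _write_ascii(grid, path)
    elif suffix in _TIFF_SUFFIXES:
        _write_geotiff(grid, path)
    else:
        raise GridFormatError(f"unsupported raster format {suffix!r} (use .tif/.tiff or .asc)")
    return path


def _read_ascii(path: Path, kind: str) -> Grid:
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
            "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise GridFormatError(f"ESRI ASCII header of {path} is missing {req}")
    try:
        values = np.loadtxt(lines[data_start:], ndmin=2)
    except ValueError as exc:  # pragma: no cover - malformed body
        raise GridFormatError(f"could not parse ASCII grid body of {path}: {exc}") from None
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise GridFormatError(
            f"ASCII grid body shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    if "xllcorner" in header:
        xll = header["xllcorner"]
    else:
        xll = header.get("xllcenter", 0.0) - cell / 2
    if "yllcorner" in header:
        yll = header["yllcorner"]
    else:
        yll = header.get("yllcenter", 0.0) - cell / 2
    nodata = header.get("nodata_value")
    return Grid(values=values, pixel_size=cell, origin=(xll, yll + nrows * cell), nodata=nodata, kind=kind)


def _format_number(v: float) -> str:
    if math.isnan(v):
        return "nan"
    if math.isfinite(v) and float(v) == int(v):
        return str(int(v))
    return np.format_float_positional(v, unique=True, trim="0")


def _write_ascii(grid: Grid, path: Path) -> None:
    ox, oy = grid.origin
    header = [
        f"ncols {grid.cols}",
        f"nrows {grid.rows}",
        f"xllcorner {_format_number(ox)}",
        f"yllcorner {_format_number(oy - grid.rows * grid.pixel_size)}",
        f"cellsize {_format_number(grid.pixel_size)}",
    ]
    if grid.nodata is not None:
        header.append(f"NODATA_value {_format_number(grid.nodata)}")
    fmt = "%d" if np.issubdtype(grid.values.dtype, np.integer) else "%.17g"
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, grid.values, fmt=fmt)


# GeoTIFF tag ids: ModelPixelScale, ModelTiepoint, GDAL nodata.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _write_geotiff(grid: Grid, path: Path) -> None:
    import tifffile

    px = grid.pixel_size
    ox, oy = grid.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (px, px, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0), True),
    ]
    if grid.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, _format_number(grid.nodata), True))
    tifffile.imwrite(path, grid.values, photometric="minisblack", extratags=extratags)


def _read_geotiff(path: Path, kind: str) -> Grid:
    import tifffile

    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:
        raise GridFormatError(f"could not read {path} as TIFF: {exc}") from None
    with tif:
        if len(tif.pages) > 1:
            raise UnsupportedInputError(f"{path} has {len(tif.pages)} pages; expected a single band")
        page = tif.pages[0]
        if getattr(page, "samplesperpixel", 1) > 1:
            raise UnsupportedInputError(
                f"{path} has {page.samplesperpixel} samples per pixel; expected a single band"
            )
        values = page.asarray()
        pixel_size = 1.0
        origin = (0.0, float(values.shape[0]))
        nodata: float | None = None
        tag = page.tags.get(_TAG_PIXEL_SCALE)
        if tag is not None:
            pixel_size = float(tag.value[0])
        tag = page.tags.get(_TAG_TIEPOINT)
        if tag is not None:
            tp = tag.value
            origin = (float(tp[3]) - float(tp[0]) * pixel_size, float(tp[4]) + float(tp[1]) * pixel_size)
        tag = page.tags.get(_TAG_GDAL_NODATA)
        if tag is not None:
            raw = tag.value.strip("\x00").strip()
            nodata = float(raw)
            if math.isfinite(nodata) and nodata == int(nodata) and np.issubdtype(values.dtype, np.integer):
                nodata = int(nodata)
    return Grid(values=values, pixel_size=pixel_size, origin=origin, nodata=nodata, kind=kind)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to(grid: Grid, template: Grid, method: Literal["nearest", "bilinear"]) -> Grid:
    """Resample ``grid`` onto the geometry of ``template``.

    ``nearest`` is mandatory for categorical grids; ``bilinear`` output is a
    convex combination of the contributing input neighbourhood, so values stay
    within its min/max.  Cells whose bilinear stencil touches nodata become
    nodata.
    """
    if method not in ("nearest", "bilinear"):
        raise InvalidMethodError(f"unknown resampling method {method!r}")
    if grid.kind == "categorical" and method != "nearest":
        raise InvalidMethodError("bilinear resampling is invalid for categorical grids")
    X, Y = template.cell_centers()
    fr = (grid.origin[1] - Y) / grid.pixel_size - 0.5
    fc = (X - grid.origin[0]) / grid.pixel_size - 0.5
    if method == "nearest":
        r = np.clip(np.rint(fr).astype(int), 0, grid.rows - 1)
        c = np.clip(np.rint(fc).astype(int), 0, grid.cols - 1)
        values = grid.values[r, c]
    else:
        coords = np.stack([fr, fc])
        values = ndimage.map_coordinates(
            grid.values.astype(float), coords, order=1, mode="nearest"
        )
        if grid.nodata is not None:
            invalid = (~grid.valid_mask).astype(float)
            touched = ndimage.map_coordinates(invalid, coords, order=1, mode="nearest")
            values = np.where(touched > 0, grid.nodata, values)
    return Grid(
        values=values,
        pixel_size=template.pixel_size,
        origin=template.origin,
        nodata=grid.nodata,
        kind=grid.kind,
    )


# ---------------------------------------------------------------------------
# Terrain derivatives
# ---------------------------------------------------------------------------

def _horn_gradients(dem: Grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dz/dx_east, dz/dy_north, window_valid) via the Horn 3x3 kernel.

    Edges use odd-reflection padding, which is exact for planes and acts as a
    one-sided difference; any window containing nodata yields an invalid cell.
    """
    z = dem.values.astype(float)
    valid = dem.valid_mask
    if not valid.any():
        raise EmptyResultError("DEM has no valid cells")
    z = np.where(valid, z, np.nan)
    zp = np.pad(z, 1, mode="reflect", reflect_type="odd")
    a, b, c = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    d, f = zp[1:-1, :-2], zp[1:-1, 2:]
    g, h, i = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    px = dem.pixel_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * px)
    dzdn = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * px)
    # the 3x3 window includes the centre cell: nodata there invalidates it too
    window_valid = valid & ~(np.isnan(dzdx) | np.isnan(dzdn))
    return dzdx, dzdn, window_valid


def derive_slope(dem: Grid) -> Grid:
    """Slope in degrees, in ``[0, 90)``; nodata propagates through 3x3 windows."""
    dzdx, dzdn, ok = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdn)))
    slope = np.where(ok, slope, np.nan)
    return dem.with_values(slope, kind="continuous", nodata=np.nan)


def derive_aspect(dem: Grid) -> Grid:
    """Aspect in degrees clockwise from north toward steepest downslope.

    Flat cells (zero gradient) get the sentinel ``-1``.
    """
    dzdx, dzdn, ok = _horn_gradients(dem)
    az = np.degrees(np.arctan2(-dzdx, -dzdn)) % 360.0
    flat = (dzdx == 0) & (dzdn == 0)
    aspect = np.where(flat, FLAT_ASPECT, az)
    aspect = np.where(ok, aspect, np.nan)
    return dem.with_values(aspect, kind="continuous", nodata=np.nan)


def _d8_receivers(dem: Grid) -> np.ndarray:
    """Flat index of each cell's steepest-descent neighbour, or -1 for pits/flats.

    Ties are broken deterministically by the fixed N, NE, E, SE, S, SW, W, NW
    neighbour order (the first neighbour attaining the maximal drop rate wins).
    """
    z = np.where(dem.valid_mask, dem.values.astype(float), np.nan)
    nrows, ncols = z.shape
    best_rate = np.full(z.shape, 0.0)
    receiver = np.full(z.shape, -1, dtype=np.int64)
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    for dr, dc in _D8_OFFSETS:
        nz = np.full(z.shape, np.nan)
        src = (slice(max(0, -dr), nrows - max(0, dr)), slice(max(0, -dc), ncols - max(0, dc)))
        dst = (slice(max(0, dr), nrows - max(0, -dr)), slice(max(0, dc), ncols - max(0, -dc)))
        nz[src] = z[dst]
        dist = dem.pixel_size * math.hypot(dr, dc)
        rate = (z - nz) / dist
        better = np.isfinite(rate) & (rate > best_rate)
        best_rate = np.where(better, rate, best_rate)
        nbr_index = (rr + dr) * ncols + (cc + dc)
        receiver = np.where(better, nbr_index, receiver)
    receiver[~dem.valid_mask] = -1
    return receiver.ravel()


def _flow_accumulation(dem: Grid) -> np.ndarray:
    """D8 flow accumulation in cells (each cell contributes itself)."""
    z = np.where(dem.valid_mask, dem.values.astype(float), np.nan)
    receiver = _d8_receivers(dem)
    acc = np.where(dem.valid_mask, 1.0, np.nan).ravel()
    flat_z = z.ravel()
    order = np.argsort(-flat_z, kind="stable")  # high to low; NaN sorts first, skipped below
    for idx in order:
        if not np.isfinite(flat_z[idx]):
            continue
        rec = receiver[idx]
        if rec >= 0:
            acc[rec] += acc[idx]
    return acc.reshape(dem.shape)


def derive_twi(dem: Grid, eps: float = 1e-6) -> Grid:
    """Topographic wetness index ``ln(a / tan(beta))``.

    ``a`` is the specific catchment area (D8 accumulation x cell area / cell
    width) and ``beta`` the Horn slope; ``tan(beta)`` is floored at ``eps`` so
    flat cells stay finite.  Invariant to adding a constant to the DEM.
    """
    slope = derive_slope(dem)
    acc = _flow_accumulation(dem)
    a = acc * dem.pixel_size  # cells * area / width = cells * pixel_size
    tanb = np.tan(np.radians(slope.values))
    tanb = np.maximum(tanb, eps)
    twi = np.log(a / tanb)
    twi = np.where(dem.valid_mask & np.isfinite(twi), twi, np.nan)
    return dem.with_values(twi, kind="continuous", nodata=np.nan)


# ---------------------------------------------------------------------------
# Distance from roads
# ---------------------------------------------------------------------------

def read_lines_geojson(source: str | Path | dict) -> list[shapely.Geometry]:
    """Polylines from a GeoJSON file, string or mapping (LineString/MultiLineString)."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        with open(source) as fh:
            obj = json.load(fh)
    elif isinstance(source, str):
        obj = json.loads(source)
    else:
        obj = source
    geoms: list[shapely.Geometry] = []
    if obj.get("type") == "FeatureCollection":
        members = [f["geometry"] for f in obj["features"]]
    elif obj.get("type") == "Feature":
        members = [obj["geometry"]]
    else:
        members = [obj]
    for g in members:
        geom = _geojson_shape(g)
        if geom.geom_type not in ("LineString", "MultiLineString"):
            raise InvalidInputError(f"expected polylines, got {geom.geom_type}")
        geoms.append(geom)
    return geoms


def distance_from_lines(template: Grid, lines: Iterable[shapely.Geometry] | shapely.Geometry) -> Grid:
    """Per-cell Euclidean distance (metres) from cell centres to the nearest polyline."""
    if isinstance(lines, shapely.Geometry):
        lines = [lines]
    lines = list(lines)
    if not lines:
        raise InvalidInputError("empty line set")
    X, Y = template.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    # min over geometries rather than a union: GEOS unions collapse
    # zero-length (degenerate point-like) segments to empty geometry
    dist = np.full(pts.shape, np.inf)
    for geom in lines:
        if not geom.is_empty:
            dist = np.minimum(dist, shapely.distance(pts, geom))
    if not np.isfinite(dist).any():
        raise InvalidInputError("line set has no geometry")
    dist = dist.reshape(template.shape)
    return Grid(
        values=dist,
        pixel_size=template.pixel_size,
        origin=template.origin,
        nodata=None,
        kind="continuous",
    )
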