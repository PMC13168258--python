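"""Equal-area grid abstraction and core raster operations.

Everything downstream (baseline construction, scenario building, social
profiling) works on a planar equal-area grid of square cells.  The default
cell side is 5 km, i.e. 25 km^2 cells, the planning-unit resolution used for
global 30x30 analyses.  Because every operation here depends only on cells
having constant area, a planar frame is an exact stand-in for an equal-area
map projection such as Mollweide.

Conventions
-----------
* Cell indexing is row-major and 0-based; cell ``(0, 0)`` sits at the origin
  corner and the center of cell ``(r, c)`` is at
  ``origin + (index + 0.5) * cell_size`` in each axis.
* ``nodata`` cells (NaN for continuous/count layers, a sentinel code for
  categorical layers) are excluded from every sum and mean and never count
  as land.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry


class GridMismatchError(ValueError):
    """Two grid-bound objects do not share the same grid."""


class GeometryError(ValueError):
    """A geometry record is invalid; the message carries the record id."""


class ZeroWeightError(ValueError):
    """A weighted statistic is undefined because the total weight is zero."""


CATEGORICAL_NODATA = -1


@dataclass(frozen=True)
class Grid:
    """Planar equal-area grid of square cells.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; must be positive.
    cell_size_km : float
        Side length of a cell in km (default 5 km -> 25 km^2 cells).
    origin_x_km, origin_y_km : float
        Coordinates of the grid's origin corner.
    projection_tag : str
        Free-text label for the equal-area planar frame.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 5.0
    origin_x_km: float = 0.0
    origin_y_km: float = 0.0
    projection_tag: str = "equal-area-planar"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def x_centers(self) -> np.ndarray:
        return self.origin_x_km + (np.arange(self.n_cols) + 0.5) * self.cell_size_km

    def y_centers(self) -> np.ndarray:
        return self.origin_y_km + (np.arange(self.n_rows) + 0.5) * self.cell_size_km

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center (x, y), row-major order."""
        xs = self.x_centers()
        ys = self.y_centers()
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def cell_box(self, row: int, col: int) -> BaseGeometry:
        s = self.cell_size_km
        x0 = self.origin_x_km + col * s
        y0 = self.origin_y_km + row * s
        return shapely.box(x0, y0, x0 + s, y0 + s)

    def extent_box(self) -> BaseGeometry:
        return shapely.box(
            self.origin_x_km,
            self.origin_y_km,
            self.origin_x_km + self.n_cols * self.cell_size_km,
            self.origin_y_km + self.n_rows * self.cell_size_km,
        )


@dataclass
class RasterLayer:
    """A gridded quantity: continuous, count (non-negative) or categorical.

    Continuous and count layers are stored as float arrays with NaN as the
    nodata marker.  Categorical layers are integer arrays with
    ``CATEGORICAL_NODATA`` (-1) as the nodata code.
    """

    grid: Grid
    values: np.ndarray
    kind: str = "continuous"  # continuous | categorical | count
    nodata: float | int = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical", "count"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind == "categorical":
            self.values = self.values.astype(np.int64, copy=False)
            if np.isnan(self.nodata):
                self.nodata = CATEGORICAL_NODATA
        else:
            self.values = self.values.astype(np.float64, copy=False)
            valid = self.values[~np.isnan(self.values)]
            if self.kind == "count" and valid.size and np.any(valid < -1e-9):
                raise ValueError("count layer has negative values")

    def nodata_mask(self) -> np.ndarray:
        if self.kind == "categorical":
            return self.values == self.nodata
        return np.isnan(self.values)

    def copy(self) -> "RasterLayer":
        return RasterLayer(self.grid, self.values.copy(), self.kind, self.nodata)


@dataclass
class CellMask:
    """Boolean selection of grid cells (a zone)."""

    grid: Grid
    included: np.ndarray

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.included.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_cells(self) -> int:
        return int(self.included.sum())

    @property
    def area_km2(self) -> float:
        return self.n_cells * self.grid.cell_area_km2

    def coverage_fraction(self, land: "CellMask") -> float:
        _check_same_grid(self.grid, land.grid)
        n_land = land.n_cells
        if n_land == 0:
            raise ZeroWeightError("land mask is empty")
        return int((self.included & land.included).sum()) / n_land

    def union(self, other: "CellMask") -> "CellMask":
        _check_same_grid(self.grid, other.grid)
        return CellMask(self.grid, self.included | other.included)

    def intersection(self, other: "CellMask") -> "CellMask":
        _check_same_grid(self.grid, other.grid)
        return CellMask(self.grid, self.included & other.included)

    def difference(self, other: "CellMask") -> "CellMask":
        _check_same_grid(self.grid, other.grid)
        return CellMask(self.grid, self.included & ~other.included)

    __or__ = union
    __and__ = intersection
    __sub__ = difference

    @classmethod
    def empty(cls, grid: Grid) -> "CellMask":
        return cls(grid, np.zeros(grid.shape, dtype=bool))

    @classmethod
    def full(cls, grid: Grid) -> "CellMask":
        return cls(grid, np.ones(grid.shape, dtype=bool))


def _check_same_grid(a: Grid, b: Grid) -> None:
    if a != b:
        raise GridMismatchError(f"grids differ: {a} vs {b}")


def _normalize_records(
    records: Iterable,
) -> list[tuple[str, BaseGeometry]]:
    out = []
    for i, rec in enumerate(records):
        if isinstance(rec, tuple):
            rid, geom = rec
        else:
            rid, geom = str(i), rec
        out.append((str(rid), geom))
    return out


def rasterize_coverage(records: Iterable, grid: Grid) -> RasterLayer:
    """Fraction of each cell covered by the union of the input geometries.

    Parameters
    ----------
    records : iterable of shapely geometries or ``(id, geometry)`` pairs
        Geometries in the grid's planar frame.
    grid : Grid

    Returns
    -------
    RasterLayer
        Continuous layer in [0, 1].  Overlapping geometries are unioned
        first, so coverage never exceeds 1.

    Raises
    ------
    GeometryError
        If a geometry is invalid (e.g. self-intersecting); the record id is
        reported.
    """
    recs = _normalize_records(records)
    for rid, geom in recs:
        if geom is None or not geom.is_valid:
            raise GeometryError(f"invalid geometry in record {rid!r}")
    frac = np.zeros(grid.shape, dtype=np.float64)
    if not recs:
        return RasterLayer(grid, frac, kind="continuous")
    union = shapely.unary_union([g for _, g in recs])
    if union.is_empty:
        return RasterLayer(grid, frac, kind="continuous")

    s = grid.cell_size_km
    minx, miny, maxx, maxy = union.bounds
    c0 = max(0, int(math.floor((minx - grid.origin_x_km) / s)))
    c1 = min(grid.n_cols, int(math.ceil((maxx - grid.origin_x_km) / s)))
    r0 = max(0, int(math.floor((miny - grid.origin_y_km) / s)))
    r1 = min(grid.n_rows, int(math.ceil((maxy - grid.origin_y_km) / s)))
    if c0 >= c1 or r0 >= r1:
        return RasterLayer(grid, frac, kind="continuous")

    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    cc, rr = np.meshgrid(cols, rows)
    x0 = grid.origin_x_km + cc.ravel() * s
    y0 = grid.origin_y_km + rr.ravel() * s
    boxes = shapely.box(x0, y0, x0 + s, y0 + s)
    areas = shapely.area(shapely.intersection(boxes, union))
    frac[r0:r1, c0:c1] = (areas / grid.cell_area_km2).reshape(len(rows), len(cols))
    np.clip(frac, 0.0, 1.0, out=frac)
    return RasterLayer(grid, frac, kind="continuous")


def threshold_mask(coverage: RasterLayer, theta: float = 0.5) -> CellMask:
    """Classify cells whose coverage fraction is >= ``theta`` (inclusive).

    The inclusive threshold mirrors the ">=50% coverage" classification rule
    for protected/conserved cells.  nodata cells are excluded.
    """
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    vals = coverage.values
    with np.errstate(invalid="ignore"):
        inc = vals >= theta
    inc &= ~coverage.nodata_mask()
    return CellMask(coverage.grid, inc)


def regrid(layer: RasterLayer, factor: int, method: str) -> RasterLayer:
    """Aggregate a layer onto a coarser grid by an integer factor.

    ``sum`` conserves the global total exactly (used for population counts),
    ``mean`` averages (used for continuous indices such as the NCP rank) and
    ``mode`` keeps the most frequent category, ties broken by the lowest
    category code.  nodata cells are excluded; an all-nodata block stays
    nodata.
    """
    if factor <= 0 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    R, C = layer.grid.shape
    if R % factor or C % factor:
        pr = (factor - R % factor) % factor
        pc = (factor - C % factor) % factor
        raise ValueError(
            f"grid {R}x{C} not divisible by factor {factor}; "
            f"pad {pr} row(s) and {pc} col(s) first"
        )
    if method not in ("sum", "mean", "mode"):
        raise ValueError(f"unknown regrid method {method!r}")
    if method == "mode" and layer.kind != "categorical":
        raise ValueError("mode regrid requires a categorical layer")
    if method in ("sum", "mean") and layer.kind == "categorical":
        raise ValueError(f"{method} regrid requires a count/continuous layer")

    nr, nc = R // factor, C // factor
    out_grid = Grid(
        nr,
        nc,
        layer.grid.cell_size_km * factor,
        layer.grid.origin_x_km,
        layer.grid.origin_y_km,
        layer.grid.projection_tag,
    )
    blocks = layer.values.reshape(nr, factor, nc, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(nr, nc, factor * factor)

    if method == "mode":
        nod = int(layer.nodata)
        out = np.full((nr, nc), nod, dtype=np.int64)
        for i in range(nr):
            for j in range(nc):
                b = blocks[i, j]
                b = b[b != nod]
                if b.size == 0:
                    continue
                cats, counts = np.unique(b, return_counts=True)
                # np.unique sorts ascending, argmax takes the first maximal
                # count, hence the lowest code on ties.
                out[i, j] = cats[np.argmax(counts)]
        return RasterLayer(out_grid, out, kind="categorical", nodata=nod)

    valid = ~np.isnan(blocks)
    n_valid = valid.sum(axis=2)
    sums = np.nansum(blocks, axis=2)
    if method == "sum":
        out = np.where(n_valid > 0, sums, np.nan)
    else:
        out = np.divide(
            sums, n_valid, out=np.full(sums.shape, np.nan), where=n_valid > 0
        )
    return RasterLayer(out_grid, out, kind=layer.kind)


def buffer_mask(mask: CellMask, distance_km: float) -> CellMask:
    """Cells outside ``mask`` whose center lies within ``distance_km`` of a
    mask-cell center (planar Euclidean distance).

    The returned ring is disjoint from ``mask`` and nested in distance:
    ``buffer(d1) <= buffer(d2)`` whenever ``d1 <= d2``.  An empty mask yields
    an empty buffer.  ``distance_km = 0`` yields an empty buffer, since the
    only cells at distance 0 are the mask cells themselves.
    """
    if distance_km < 0:
        raise ValueError("distance_km must be non-negative")
    inc = mask.included
    if not inc.any() or distance_km == 0:
        return CellMask.empty(mask.grid)
    centers = mask.grid.cell_centers()
    tree = cKDTree(centers[inc.ravel()])
    d, _ = tree.query(centers, k=1, distance_upper_bound=distance_km * (1 + 1e-12) + 1e-9)
    near = (d <= distance_km * (1 + 1e-12) + 1e-9).reshape(mask.grid.shape)
    return CellMask(mask.grid, near & ~inc)


def zonal_sum(layer: RasterLayer, mask: CellMask) -> float:
    """Sum of non-nodata layer values over the masked cells (0 if empty)."""
    _check_same_grid(layer.grid, mask.grid)
    if layer.kind == "categorical":
        raise ValueError("zonal_sum requires a count or continuous layer")
    vals = layer.values[mask.included]
    return float(np.nansum(vals))


def zonal_weighted_mean(
    value: RasterLayer, weight: RasterLayer, mask: CellMask
) -> float:
    """Weight-averaged value over the masked cells.

    Cells where either layer is nodata are dropped.  A zero total weight is
    an undefined statistic and raises :class:`ZeroWeightError` rather than
    silently returning 0.
    """
    _check_same_grid(value.grid, weight.grid)
    _check_same_grid(value.grid, mask.grid)
    v = value.values[mask.included]
    w = weight.values[mask.included]
    ok = ~np.isnan(v) & ~np.isnan(w)
    if np.any(w[ok] < 0):
        raise ValueError("weights must be non-negative")
    tot = float(np.sum(w[ok]))
    if tot == 0.0:
        raise ZeroWeightError("total weight over the zone is zero")
    return float(np.sum(v[ok] * w[ok]) / tot)
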