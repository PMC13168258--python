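"""Current protected/conserved-area network from database-style records.

Implements the Protected Planet-style filtering rules used for Target 3
reporting: proposed protected areas and UNESCO-MAB biosphere reserves are
excluded, all OECMs are retained, marine records are removed, and
point-format records with a reported area are replaced by an equal-area
circle around the point (records without a reported area are discarded).
The kept geometries are rasterized to per-cell coverage fractions and cells
with >=50% coverage form the baseline network mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import (
    CellMask,
    Grid,
    RasterLayer,
    rasterize_coverage,
    threshold_mask,
)

VALID_STATUS = {"proposed", "designated", "inscribed", "established", "adopted"}
VALID_CATEGORY = {"PA", "OECM"}
VALID_REALM = {"terrestrial", "marine", "coastal"}

#: number of vertices of the polygon standing in for a point-buffer circle
CIRCLE_VERTICES = 64


@dataclass
class PARecord:
    """One protected-area / OECM database entry."""

    id: str
    status: str = "designated"
    category: str = "PA"
    designation_flag: str = "none"  # none | MAB_biosphere
    realm: str = "terrestrial"
    geometry_kind: str = "polygon"  # polygon | point
    geometry: BaseGeometry | None = None
    reported_area_km2: float | None = None

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUS:
            raise ValueError(f"record {self.id}: unknown status {self.status!r}")
        if self.category not in VALID_CATEGORY:
            raise ValueError(f"record {self.id}: unknown category {self.category!r}")
        if self.realm not in VALID_REALM:
            raise ValueError(f"record {self.id}: unknown realm {self.realm!r}")
        if self.geometry_kind not in ("polygon", "point"):
            raise ValueError(
                f"record {self.id}: unknown geometry_kind {self.geometry_kind!r}"
            )


@dataclass
class AuditEntry:
    id: str
    disposition: str  # kept | buffered_point | dropped:<reason>

    @property
    def kept(self) -> bool:
        return not self.disposition.startswith("dropped")


@dataclass
class BaselineNetwork:
    """The current protected-and-conserved mask plus its provenance."""

    mask: CellMask
    coverage_fraction: float
    audit: list[AuditEntry]
    coverage: RasterLayer | None = field(default=None, repr=False)

    def kept_ids(self) -> list[str]:
        return [a.id for a in self.audit if a.kept]


def area_circle(center, area_km2: float, n_vertices: int = CIRCLE_VERTICES):
    """Regular polygon centered on ``center`` whose *polygon* area equals
    ``area_km2`` exactly.

    A regular n-gon inscribed in a circle of radius r has area
    (n/2) r^2 sin(2*pi/n), slightly below pi r^2; the radius is inflated to
    compensate so the reported area is preserved (well within the documented
    0.1% tolerance).
    """
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    n = n_vertices
    r = math.sqrt(2.0 * area_km2 / (n * math.sin(2.0 * math.pi / n)))
    cx, cy = center.x, center.y
    ang = 2.0 * np.pi * np.arange(n) / n
    coords = np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])
    return shapely.polygons(coords)


def filter_records(
    records: list[PARecord],
) -> tuple[list[tuple[str, BaseGeometry]], list[AuditEntry]]:
    """Apply the Target 3 reporting filter to raw records.

    Returns the kept ``(id, geometry)`` list and an audit with exactly one
    disposition per input record.

    Rules, in order: negative reported area -> rejected; marine records
    dropped; proposed-status *PAs* dropped (OECMs are kept regardless of
    status); MAB-biosphere-flagged *PAs* dropped; invalid polygon geometry
    rejected; point records with a reported area replaced by an equal-area
    circle, without one dropped.
    """
    kept: list[tuple[str, BaseGeometry]] = []
    audit: list[AuditEntry] = []
    for rec in records:
        if rec.reported_area_km2 is not None and rec.reported_area_km2 < 0:
            audit.append(AuditEntry(rec.id, "dropped:negative_area"))
            continue
        if rec.realm == "marine":
            audit.append(AuditEntry(rec.id, "dropped:marine"))
            continue
        if rec.category == "PA" and rec.status == "proposed":
            audit.append(AuditEntry(rec.id, "dropped:proposed"))
            continue
        if rec.category == "PA" and rec.designation_flag == "MAB_biosphere":
            audit.append(AuditEntry(rec.id, "dropped:mab"))
            continue
        if rec.geometry_kind == "point":
            if rec.reported_area_km2 is None or rec.reported_area_km2 == 0:
                audit.append(AuditEntry(rec.id, "dropped:no_area"))
                continue
            if rec.geometry is None:
                audit.append(AuditEntry(rec.id, "dropped:invalid_geometry"))
                continue
            circle = area_circle(rec.geometry, rec.reported_area_km2)
            kept.append((rec.id, circle))
            audit.append(AuditEntry(rec.id, "buffered_point"))
            continue
        if rec.geometry is None or not rec.geometry.is_valid:
            audit.append(AuditEntry(rec.id, "dropped:invalid_geometry"))
            continue
        kept.append((rec.id, rec.geometry))
        audit.append(AuditEntry(rec.id, "kept"))
    return kept, audit


def build_baseline(
    records: list[PARecord], grid: Grid, land: CellMask | None = None
) -> BaselineNetwork:
    """Filter records, rasterize coverage and threshold at 50%.

    If a land mask is given, geometries are clipped to the union of land
    cells before coverage is computed (the grid-level equivalent of removing
    marine portions of coastal areas) and the coverage fraction is reported
    relative to land; otherwise relative to the whole grid.
    """
    kept, audit = filter_records(records)
    geoms = kept
    if land is not None and kept:
        land_poly = _mask_polygon(land)
        clipped = []
        for rid, geom in kept:
            g = geom.intersection(land_poly)
            if not g.is_empty:
                clipped.append((rid, g))
        geoms = clipped
    coverage = rasterize_coverage(geoms, grid)
    mask = threshold_mask(coverage, 0.5)
    if land is not None:
        mask = mask & land
        frac = mask.coverage_fraction(land) if land.n_cells else 0.0
    else:
        frac = mask.n_cells / grid.n_cells
    return BaselineNetwork(mask=mask, coverage_fraction=frac, audit=audit, coverage=coverage)


def _mask_polygon(mask: CellMask) -> BaseGeometry:
    """Union polygon of all included cells."""
    rows, cols = np.nonzero(mask.included)
    if rows.size == 0:
        return shapely.Polygon()
    s = mask.grid.cell_size_km
    x0 = mask.grid.origin_x_km + cols * s
    y0 = mask.grid.origin_y_km + rows * s
    boxes = shapely.box(x0, y0, x0 + s, y0 + s)
    return shapely.unary_union(boxes)
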