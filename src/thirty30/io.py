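"""File I/O: text rasters (ESRI ASCII grid), GeoJSON geometries, tables.

Rasters are written as single-band ESRI ASCII grids (``.asc``), a plain-text
format readable by terra/GDAL/QGIS; masks are 0/1 grids.  Geometry lists and
protected-area records travel as GeoJSON FeatureCollections with the record
attributes in ``properties``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .baseline import AuditEntry, PARecord
from .grid import CATEGORICAL_NODATA, CellMask, Grid, RasterLayer

_ASC_NODATA = -9999.0


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (rows top-to-bottom)."""
    grid = layer.grid
    if layer.kind == "categorical":
        vals = layer.values.astype(float)
        vals[layer.values == layer.nodata] = _ASC_NODATA
        fmt = "%d"
    else:
        vals = np.where(np.isnan(layer.values), _ASC_NODATA, layer.values)
        fmt = "%.10g"
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x_km}\n"
        f"yllcorner {grid.origin_y_km}\n"
        f"cellsize {grid.cell_size_km}\n"
        f"NODATA_value {int(_ASC_NODATA)}\n"
    )
    # ESRI convention: first data row is the northernmost (max y); our row 0
    # is at the origin (min y), so flip vertically on write.
    body = "\n".join(
        " ".join(fmt % v for v in row) for row in vals[::-1]
    )
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path, kind: str = "continuous") -> RasterLayer:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    grid = Grid(
        int(hdr["nrows"]), int(hdr["ncols"]),
        hdr["cellsize"], hdr["xllcorner"], hdr["yllcorner"],
    )
    data = np.loadtxt(lines[i:], dtype=float).reshape(grid.shape)[::-1]
    nod = hdr.get("nodata_value", _ASC_NODATA)
    if kind == "categorical":
        vals = data.astype(np.int64)
        vals[data == nod] = CATEGORICAL_NODATA
        return RasterLayer(grid, vals, kind="categorical", nodata=CATEGORICAL_NODATA)
    vals = np.where(data == nod, np.nan, data)
    return RasterLayer(grid, vals, kind=kind)


def write_mask(mask: CellMask, path: str | Path) -> None:
    write_ascii_grid(
        RasterLayer(mask.grid, mask.included.astype(float), kind="continuous"), path
    )


def read_mask(path: str | Path) -> CellMask:
    layer = read_ascii_grid(path, kind="continuous")
    return CellMask(layer.grid, np.nan_to_num(layer.values) >= 0.5)


# --------------------------------------------------------------------------
# GeoJSON
# --------------------------------------------------------------------------

def _geom_to_json(geom) -> dict | None:
    if geom is None:
        return None
    return json.loads(shapely.to_geojson(geom))


def _geom_from_json(obj) -> shapely.Geometry | None:
    if obj is None:
        return None
    return shapely.from_geojson(json.dumps(obj))


def write_pa_records(records: list[PARecord], path: str | Path) -> None:
    feats = []
    for r in records:
        props = {
            "id": r.id,
            "status": r.status,
            "category": r.category,
            "designation_flag": r.designation_flag,
            "realm": r.realm,
            "geometry_kind": r.geometry_kind,
            "reported_area_km2": r.reported_area_km2,
        }
        feats.append(
            {"type": "Feature", "geometry": _geom_to_json(r.geometry), "properties": props}
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_pa_records(path: str | Path) -> list[PARecord]:
    fc = json.loads(Path(path).read_text())
    out = []
    for feat in fc["features"]:
        p = feat["properties"]
        out.append(
            PARecord(
                id=p["id"],
                status=p.get("status", "designated"),
                category=p.get("category", "PA"),
                designation_flag=p.get("designation_flag", "none"),
                realm=p.get("realm", "terrestrial"),
                geometry_kind=p.get("geometry_kind", "polygon"),
                geometry=_geom_from_json(feat.get("geometry")),
                reported_area_km2=p.get("reported_area_km2"),
            )
        )
    return out


def write_iplc_lands(
    lands: list[tuple[shapely.Geometry, str]], path: str | Path
) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": _geom_to_json(geom),
            "properties": {"rights_flag": flag},
        }
        for geom, flag in lands
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_iplc_lands(path: str | Path) -> list[tuple[shapely.Geometry, str]]:
    fc = json.loads(Path(path).read_text())
    return [
        (_geom_from_json(f.get("geometry")), f["properties"].get("rights_flag", "none"))
        for f in fc["features"]
    ]


def write_audit(audit: list[AuditEntry], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": a.id, "disposition": a.disposition} for a in audit]
    ).to_csv(path, index=False)


def read_audit(path: str | Path) -> list[AuditEntry]:
    df = pd.read_csv(path)
    return [AuditEntry(str(r.id), str(r.disposition)) for r in df.itertuples()]
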