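"""Text exports: GeoJSON for geometries, YAML/CSV for parameters and tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping

from .track_io import unproject

__all__ = ["polygon_to_geojson_feature", "write_geojson", "points_to_geojson"]


def _unproject_ring(ring, center):
    arr = np.asarray(ring, dtype=float)
    lon, lat = unproject(arr[:, 0], arr[:, 1], center)
    return [[float(a), float(b)] for a, b in zip(lon, lat)]


def polygon_to_geojson_feature(geom, center: tuple[float, float], properties: dict | None = None) -> dict:
    """Shapely (Multi)Polygon in projected metres -> GeoJSON feature in lon/lat."""
    m = mapping(geom)
    if m["type"] == "Polygon":
        coords = [_unproject_ring(r, center) for r in m["coordinates"]]
    elif m["type"] == "MultiPolygon":
        coords = [[_unproject_ring(r, center) for r in poly] for poly in m["coordinates"]]
    elif m["type"] == "GeometryCollection":
        polys = [g for g in geom.geoms if isinstance(g, (shapely.Polygon, shapely.MultiPolygon))]
        return polygon_to_geojson_feature(shapely.union_all(polys), center, properties)
    else:
        raise ValueError(f"unsupported geometry type {m['type']}")
    return {
        "type": "Feature",
        "geometry": {"type": m["type"], "coordinates": coords},
        "properties": properties or {},
    }


def points_to_geojson(lons, lats, properties_per_point: list[dict]) -> dict:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(lon), float(lat)]},
            "properties": props,
        }
        for lon, lat, props in zip(lons, lats, properties_per_point)
    ]
    return {"type": "FeatureCollection", "features": features}


def write_geojson(features: list[dict] | dict, path: str | Path) -> None:
    obj = features if isinstance(features, dict) else {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(obj, fh)
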