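"""Readers for the pipeline's input formats.

Soil CSV: columns x, y, hg_mgkg, depth_layer, parcel_id, below_lod.
Participant CSV: the fields of :class:`hgkrige.hbm.Participant`.
Canal: GeoJSON LineString (Feature or bare geometry) or WKT LINESTRING,
in the same planar meters as the coordinates.
"""

from __future__ import annotations

import json
import pathlib

import pandas as pd
from shapely import wkt as _wkt

from .geo import Polyline

__all__ = ["read_soil_csv", "read_participants_csv", "read_canal"]

_SOIL_COLS = ("x", "y", "hg_mgkg", "depth_layer")


def read_soil_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _SOIL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"soil CSV missing columns: {missing}")
    return df


def read_participants_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("id", "family_id", "x", "y"):
        if c not in df.columns:
            raise ValueError(f"participant CSV missing column {c!r}")
    return df


def read_canal(path) -> Polyline:
    """Load the canal polyline from GeoJSON or WKT."""
    text = pathlib.Path(path).read_text().strip()
    if text.upper().startswith("LINESTRING"):
        geom = _wkt.loads(text)
        return Polyline.from_coords(list(geom.coords))
    obj = json.loads(text)
    if obj.get("type") == "Feature":
        obj = obj["geometry"]
    elif obj.get("type") == "FeatureCollection":
        obj = obj["features"][0]["geometry"]
    if obj.get("type") != "LineString":
        raise ValueError("canal geometry must be a LineString")
    return Polyline.from_coords(obj["coordinates"])
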