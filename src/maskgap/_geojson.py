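"""Minimal GeoJSON I/O for village polygon frames.

Villages travel as a pandas DataFrame with a shapely ``geometry`` column;
attributes are plain columns. Coordinates are planar (meters), so the
GeoJSON written here is a plain feature collection without a CRS member.
"""

from __future__ import annotations

import json
from typing import Iterable

import pandas as pd
from shapely.geometry import mapping, shape


def frame_to_geojson(frame: pd.DataFrame, path: str, *, precision: int = 6) -> None:
    """Write a DataFrame with a ``geometry`` column as a GeoJSON FeatureCollection."""
    features = []
    attr_cols = [c for c in frame.columns if c != "geometry"]
    for _, row in frame.iterrows():
        geom = json.loads(json.dumps(mapping(row["geometry"])))
        props = {}
        for c in attr_cols:
            v = row[c]
            if hasattr(v, "item"):
                v = v.item()
            props[c] = v
        features.append({"type": "Feature", "geometry": geom, "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def geojson_to_frame(path: str) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection into a DataFrame with a ``geometry`` column."""
    with open(path) as fh:
        fc = json.load(fh)
    rows = []
    for feat in fc["features"]:
        row = dict(feat.get("properties") or {})
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)


def ordered_columns(frame: pd.DataFrame, first: Iterable[str]) -> pd.DataFrame:
    cols = [c for c in first if c in frame.columns]
    cols += [c for c in frame.columns if c not in cols]
    return frame[cols]
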