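"""Plain-text serialisation: GeoJSON geography and CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import Point, mapping, shape


def counties_to_geojson(counties: pd.DataFrame, path) -> None:
    """Write the county set as a GeoJSON FeatureCollection.

    Geometry is the population-weighted centroid point (coordinates in
    planar km); the geometric centroid and area are carried as feature
    properties, so the full geography round-trips.
    """
    features = []
    for _, r in counties.iterrows():
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(Point(r["pw_x"], r["pw_y"])),
                "properties": {
                    "county_id": r["county_id"],
                    "region_id": int(r["region_id"]),
                    "cx": r["cx"],
                    "cy": r["cy"],
                    "area": r["area"],
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1, sort_keys=True)
    )


def counties_from_geojson(path) -> pd.DataFrame:
    """Read a county FeatureCollection back into the geography table."""
    fc = json.loads(Path(path).read_text())
    rows = []
    for feat in fc["features"]:
        pt = shape(feat["geometry"])
        props = feat["properties"]
        rows.append(
            {
                "county_id": props["county_id"],
                "region_id": props["region_id"],
                "cx": props["cx"],
                "cy": props["cy"],
                "area": props["area"],
                "pw_x": pt.x,
                "pw_y": pt.y,
            }
        )
    return pd.DataFrame(rows)


def write_csv(df: pd.DataFrame, path) -> None:
    """Deterministic CSV write (stable column order, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
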