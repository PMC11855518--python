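"""On-disk formats: event CSV, GeoJSON layers, flat key=value config.

Coordinates are planar metres in a local projection; GeoJSON is used as a
container for Point/Polygon features without any CRS reprojection.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import Point, box, mapping, shape

from .synth_city import CandidateSite, EventRecord

EVENT_COLUMNS = [
    "event_id", "x_m", "y_m", "call_datetime", "age", "sex", "traumatic",
    "response_time_s", "dispatch_time_s", "bystander_cpr", "shockable",
    "death", "cpr_duration_s", "complete",
]


def events_to_frame(events: list[EventRecord]) -> pd.DataFrame:
    rows = [
        {
            "event_id": e.event_id,
            "x_m": e.location[0],
            "y_m": e.location[1],
            "call_datetime": e.call_datetime.isoformat(),
            "age": e.age,
            "sex": e.sex,
            "traumatic": e.traumatic,
            "response_time_s": e.response_time_s,
            "dispatch_time_s": e.dispatch_time_s,
            "bystander_cpr": e.bystander_cpr,
            "shockable": e.shockable,
            "death": e.death,
            "cpr_duration_s": e.cpr_duration_s,
            "complete": e.complete,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> list[EventRecord]:
    events = []
    for row in df.itertuples(index=False):
        events.append(
            EventRecord(
                event_id=str(row.event_id),
                location=(float(row.x_m), float(row.y_m)),
                call_datetime=pd.Timestamp(row.call_datetime).to_pydatetime(),
                age=float(row.age),
                sex=str(row.sex),
                traumatic=bool(row.traumatic),
                response_time_s=float(row.response_time_s),
                dispatch_time_s=float(row.dispatch_time_s),
                bystander_cpr=str(row.bystander_cpr),
                shockable=bool(row.shockable),
                death=bool(row.death),
                cpr_duration_s=float(row.cpr_duration_s),
                complete=bool(row.complete),
            )
        )
    return events


def write_events_csv(events: list[EventRecord], path: str | Path) -> None:
    # %.17g keeps float round-trips exact
    events_to_frame(events).to_csv(path, index=False, float_format="%.17g")


def read_events_csv(path: str | Path) -> list[EventRecord]:
    return frame_to_events(pd.read_csv(path, float_precision="round_trip"))


# -- GeoJSON ----------------------------------------------------------------

def _feature(geom, props: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def city_to_geojson(city) -> dict:
    """City layers (bbox polygon, base points, candidate points) as one
    FeatureCollection distinguished by a ``layer`` property."""
    feats = [_feature(box(*city.bbox), {"layer": "bbox"})]
    for i, (x, y) in enumerate(city.bases):
        feats.append(_feature(Point(x, y), {"layer": "base", "id": f"B{i:02d}"}))
    for c in city.candidates:
        feats.append(
            _feature(
                Point(*c.location),
                {"layer": "candidate", "id": c.site_id, "label": c.label},
            )
        )
    return feature_collection(feats)


def write_city_geojson(city, path: str | Path) -> None:
    Path(path).write_text(json.dumps(city_to_geojson(city)))


def read_candidates_geojson(path: str | Path) -> list[CandidateSite]:
    gj = json.loads(Path(path).read_text())
    cands = []
    for f in gj["features"]:
        props = f.get("properties") or {}
        if props.get("layer", "candidate") != "candidate":
            continue
        geom = shape(f["geometry"])
        cands.append(
            CandidateSite(
                site_id=str(props.get("id", f"C{len(cands):04d}")),
                location=(geom.x, geom.y),
                label=str(props.get("label", "")),
            )
        )
    if not cands:
        raise ValueError(f"no candidate Point features in {path}")
    return cands


def grid_to_geojson(grid, cell_props: dict[str, list]) -> dict:
    """Square demand-grid cells as Polygon features.

    ``cell_props`` maps property name -> per-cell list aligned with
    ``grid.cells``.
    """
    half = grid.cell_size_m / 2.0
    feats = []
    for i, cell in enumerate(grid.cells):
        cx, cy = cell.centroid
        poly = box(cx - half, cy - half, cx + half, cy + half)
        props = {"cell_id": cell.cell_id, "event_count": cell.event_count}
        for k, v in cell_props.items():
            props[k] = v[i]
        feats.append(_feature(poly, props))
    return feature_collection(feats)


# -- flat config ------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key=value`` file; blank lines and '#' comments ignored."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{k}={v}\n" for k, v in cfg.items())
    )
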