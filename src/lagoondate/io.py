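"""Readers and writers for the package's file formats.

CSV carries tabular records (series, truth, fits, estimates, distances,
summaries); GeoJSON carries geometry (sites as Points, water features as
Polygons/LineStrings with ``fclass`` and ``area_km2`` properties, watershed
polygons). Dates are ISO-8601 calendar dates throughout. All coordinates are
WGS84 lon/lat.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .changepoint import ChangepointFit
from .estimator import PRE_ERA, ConstructionEstimate
from .series import ReflectanceSeries
from .spatial import LagoonSite, NearestDistanceRecord, WaterFeature
from .synth import TruthRecord

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_truth_csv",
    "write_truth_csv",
    "write_fits_csv",
    "read_estimates_csv",
    "write_estimates_csv",
    "read_distances_csv",
    "write_distances_csv",
    "read_geojson",
    "write_sites_geojson",
    "write_features_geojson",
    "write_polygons_geojson",
]


class FormatError(ValueError):
    """A file violated the expected format; the message lists the lines."""


# CSV -----------------------------------------------------------------------

def read_series_csv(path: str | Path) -> list[ReflectanceSeries]:
    """Read `site_id,date,value` rows into per-site series.

    Rows may arrive unsorted; they are grouped by site and sorted by date.
    Malformed dates/values and duplicate (site, date) pairs are reported
    with their line numbers.
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = {"site_id", "date", "value"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = dates.isna() | values.isna()
    if bad.any():
        lines = [i + 2 for i in df.index[bad]]  # +2: header + 0-based index
        raise FormatError(f"{path}: unparseable date/value on lines {lines}")
    df = df.assign(date=dates.values.astype("datetime64[D]"), value=values.values)
    dup = df.duplicated(["site_id", "date"], keep=False)
    if dup.any():
        lines = [i + 2 for i in df.index[dup]]
        raise FormatError(f"{path}: duplicate (site_id, date) rows on lines {lines}")
    out = []
    for site_id, g in df.sort_values(["site_id", "date"]).groupby("site_id", sort=True):
        out.append(
            ReflectanceSeries(str(site_id), g["date"].values, g["value"].values)
        )
    return out


def write_series_csv(series: Iterable[ReflectanceSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"site_id": s.site_id, "date": s.dates.astype(str), "value": s.values})
        for s in series
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["site_id", "date", "value"]
    )
    df.to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> dict[str, Union[int, str]]:
    """Read `site_id,true_change_year` into a mapping; allows PRE_ERA."""
    df = pd.read_csv(path, dtype={"site_id": str})
    out: dict[str, Union[int, str]] = {}
    for _, row in df.iterrows():
        raw = str(row["true_change_year"])
        out[str(row["site_id"])] = PRE_ERA if raw == PRE_ERA else int(float(raw))
    return out


def write_truth_csv(truth: Iterable[TruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(t.site_id, t.true_change_year) for t in truth],
        columns=["site_id", "true_change_year"],
    ).to_csv(path, index=False)


def write_fits_csv(fits: Iterable[ChangepointFit], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                f.site_id,
                f.tau,
                str(f.changepoint_date),
                f.s1_mean,
                f.s2_mean,
                f.cost,
                f.degenerate,
            )
            for f in fits
        ],
        columns=["site_id", "tau", "changepoint_date", "s1_mean", "s2_mean", "cost", "degenerate"],
    ).to_csv(path, index=False)


def write_estimates_csv(estimates: Iterable[ConstructionEstimate], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                e.site_id,
                e.kind,
                e.year if e.year is not None else "",
                "out_of_window" if e.out_of_window else "",
            )
            for e in estimates
        ],
        columns=["site_id", "kind", "year", "flag"],
    ).to_csv(path, index=False)


def read_estimates_csv(path: str | Path) -> list[ConstructionEstimate]:
    df = pd.read_csv(path, dtype={"site_id": str}, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        kind = str(row["kind"])
        year = int(float(row["year"])) if str(row["year"]) not in ("", "nan") else None
        out.append(
            ConstructionEstimate(
                site_id=str(row["site_id"]),
                kind=kind,
                year=year,
                out_of_window=str(row.get("flag", "")) == "out_of_window",
            )
        )
    return out


def write_distances_csv(records: Iterable[NearestDistanceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.site_id, r.feature_id, r.fclass, r.distance_m) for r in records],
        columns=["site_id", "feature_id", "fclass", "distance_m"],
    ).to_csv(path, index=False)


def read_distances_csv(path: str | Path) -> list[NearestDistanceRecord]:
    df = pd.read_csv(path, dtype={"site_id": str, "feature_id": str})
    return [
        NearestDistanceRecord(
            str(r["site_id"]), str(r["feature_id"]), str(r["fclass"]), float(r["distance_m"])
        )
        for _, r in df.iterrows()
    ]


# GeoJSON -------------------------------------------------------------------

def _load_feature_collection(path: str | Path) -> list[dict]:
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    return data["features"]


def read_geojson(
    path: str | Path, kind: str
) -> Union[list[LagoonSite], list[WaterFeature], dict[str, BaseGeometry]]:
    """Read a typed GeoJSON FeatureCollection.

    ``kind`` is ``"sites"`` (Points -> LagoonSite), ``"features"``
    (water features; require ``fclass`` and, for polygons, ``area_km2``),
    or ``"polygons"`` (watershed polygons keyed by id). Invalid geometry or
    missing required properties raise an error naming the feature.
    """
    feats = _load_feature_collection(path)
    if kind == "sites":
        sites = []
        for i, f in enumerate(feats):
            geom = shape(f["geometry"])
            if geom.geom_type != "Point":
                raise FormatError(f"{path}: site {i} is not a Point")
            props = f.get("properties") or {}
            sites.append(LagoonSite(str(props.get("site_id", f"site{i:04d}")), geom.x, geom.y))
        return sites
    if kind == "features":
        out = []
        for i, f in enumerate(feats):
            props = f.get("properties") or {}
            fid = str(props.get("feature_id", f"feat{i:04d}"))
            if "fclass" not in props:
                raise FormatError(f"{path}: feature {fid} missing required property 'fclass'")
            geom = shape(f["geometry"])
            if not geom.is_valid:
                raise FormatError(f"{path}: feature {fid} has invalid geometry")
            is_poly = geom.geom_type in ("Polygon", "MultiPolygon")
            if is_poly and "area_km2" not in props:
                raise FormatError(f"{path}: polygon feature {fid} missing 'area_km2'")
            out.append(
                WaterFeature(fid, str(props["fclass"]), geom, float(props.get("area_km2", 0.0)))
            )
        return out
    if kind == "polygons":
        polys: dict[str, BaseGeometry] = {}
        for i, f in enumerate(feats):
            props = f.get("properties") or {}
            pid = str(props.get("polygon_id", f"poly{i:04d}"))
            geom = shape(f["geometry"])
            if not geom.is_valid:
                raise FormatError(f"{path}: polygon {pid} has invalid geometry")
            if geom.geom_type not in ("Polygon", "MultiPolygon"):
                raise FormatError(f"{path}: {pid} is not polygonal")
            polys[pid] = geom
        return polys
    raise ValueError(f"unknown kind {kind!r}")


def _write_fc(features: list[dict], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def write_sites_geojson(sites: Sequence[LagoonSite], path: str | Path) -> None:
    _write_fc(
        [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [s.lon, s.lat]},
                "properties": {"site_id": s.site_id},
            }
            for s in sites
        ],
        path,
    )


def write_features_geojson(features: Sequence[WaterFeature], path: str | Path) -> None:
    _write_fc(
        [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": {
                    "feature_id": f.feature_id,
                    "fclass": f.fclass,
                    "area_km2": f.area_km2,
                },
            }
            for f in features
        ],
        path,
    )


def write_polygons_geojson(polygons: Mapping[str, BaseGeometry], path: str | Path) -> None:
    _write_fc(
        [
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"polygon_id": pid},
            }
            for pid, geom in sorted(polygons.items())
        ],
        path,
    )
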