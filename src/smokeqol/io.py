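"""Readers and writers for the pipeline's on-disk formats.

Vector inputs travel as GeoJSON FeatureCollections (one feature per plume,
``date`` property in ISO-8601); tabular artefacts are plain CSV so every
intermediate is inspectable with standard tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .geometry import PlumeRecord, StudyArea


def write_plumes_geojson(plumes: Sequence[PlumeRecord], path: str | Path) -> None:
    features = []
    for p in plumes:
        props = {"date": p.date.isoformat()}
        if p.density is not None:
            props["density"] = p.density
        features.append({"type": "Feature", "geometry": mapping(p.geometry), "properties": props})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_plumes_geojson(path: str | Path) -> list[PlumeRecord]:
    doc = json.loads(Path(path).read_text())
    out = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        if "date" not in props:
            raise ValueError(f"plume feature {i} has no 'date' property")
        out.append(PlumeRecord(
            date=props["date"],
            geometry=shape(feat["geometry"]),
            density=props.get("density"),
            label=f"feature {i}",
        ))
    return out


def write_study_area_geojson(area: StudyArea, path: str | Path) -> None:
    doc = {
        "type": "Feature",
        "geometry": mapping(area.geometry),
        "properties": {"name": area.name},
    }
    Path(path).write_text(json.dumps(doc))


def read_study_area_geojson(path: str | Path) -> StudyArea:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        feats = doc["features"]
        if len(feats) != 1:
            raise ValueError("study-area GeoJSON must contain exactly one feature")
        doc = feats[0]
    name = (doc.get("properties") or {}).get("name", "study area")
    return StudyArea(geometry=shape(doc["geometry"]), name=name)


def write_smoke_days(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="date")


def read_smoke_days(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"], index_col="date")
    df["is_smoke"] = df["is_smoke"].astype(bool)
    return df


def read_sgrq_weights(path: str | Path) -> dict[str, dict[str, float]]:
    """SGRQ item-weight table from YAML: {domain: {item: weight}}.

    The official weights are licensed and must be obtained by the user; this
    reader only validates the shape of whatever table is supplied.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or not doc:
        raise ValueError("weight table must be a non-empty mapping of domains")
    out: dict[str, dict[str, float]] = {}
    for domain, items in doc.items():
        if not isinstance(items, dict) or not items:
            raise ValueError(f"domain {domain!r} must map items to weights")
        out[str(domain)] = {str(k): float(v) for k, v in items.items()}
    return out


def write_sgrq_weights(weights: dict[str, dict[str, float]], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(weights, sort_keys=True))


def write_grid(grid: pd.DataFrame, path: str | Path) -> None:
    grid.to_csv(path, index=False)


def read_grid(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def write_ground_truth(truth, out_dir: str | Path) -> None:
    """Persist a simulation's ground truth: per-cell-day contributions as CSV,
    planted effect sizes and clamp counts as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.contributions.to_csv(out / "ground_truth_contributions.csv", index=False)
    meta = {
        "planted_betas": {f"{o}|{m}|{w}": float(b)
                          for (o, m, w), b in truth.planted_betas.items()},
        "n_smoke_days": int(len(truth.smoke_days)),
        "clamp_counts": {k: int(v) for k, v in (truth.clamp_counts or {}).items()},
    }
    (out / "ground_truth.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_external_smoke_pm25(path: str | Path, county: str | None = None) -> pd.Series:
    """Alternate exposure input: a pre-computed daily county-level smoke-PM2.5
    CSV (date, county, smoke_pm25), e.g. from a published prediction model,
    used for sensitivity analyses in place of the deviation attribution.

    Returns a date-indexed μg/m³ series; with multiple counties and no
    ``county`` selection, the across-county daily mean.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "county", "smoke_pm25"}
    if not required <= set(df.columns):
        raise ValueError(f"expected columns {sorted(required)}, got {list(df.columns)}")
    if county is not None:
        df = df[df["county"] == county]
        if df.empty:
            raise ValueError(f"no rows for county {county!r}")
    series = df.groupby("date")["smoke_pm25"].mean().sort_index()
    series.name = "smoke_pm25"
    return series
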