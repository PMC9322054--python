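"""File I/O and run configuration.

All CSV dialects are UTF-8, comma-separated, header row, "." decimal, dates
ISO-8601. Files written by this module open with a ``#``-prefixed comment
line embedding the master seed and config hash so every artifact is
traceable to the run that produced it; the readers here skip such lines.
Polygons travel as GeoJSON FeatureCollections, adjacency as a two-column
edge-list CSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping as geom_mapping, shape as geom_shape

from .exposure import StationRecord
from .geometry import AreaLattice, WeightMatrix

__all__ = [
    "RunConfig", "config_hash", "stamp",
    "read_edges_csv", "write_edges_csv",
    "read_geojson_polygons", "write_geojson_polygons",
    "read_table", "write_table",
    "read_stations", "write_stations",
    "write_weights_csv", "write_manifest",
]


# ---------------------------------------------------------------------------
# provenance helpers


def config_hash(obj) -> str:
    """Stable SHA-256 over a JSON-serialisable config object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def stamp(seed, cfg_hash: str) -> str:
    return f"# seed={seed} config={cfg_hash}\n"


def write_table(frame: pd.DataFrame, path, seed=None, cfg_hash: str = "-") -> None:
    """Write a CSV with a provenance comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(stamp(seed, cfg_hash))
        frame.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype={"area_id": str, "station_id": str})


# ---------------------------------------------------------------------------
# adjacency


def write_edges_csv(lattice: AreaLattice, path, seed=None, cfg_hash="-") -> None:
    frame = pd.DataFrame(sorted(lattice.edges), columns=["area_i", "area_j"])
    write_table(frame, path, seed, cfg_hash)


def read_edges_csv(path, area_ids: Sequence[str] | None = None) -> AreaLattice:
    """Edge-list CSV -> lattice. Ids are strings; isolated areas can only be
    represented when ``area_ids`` lists the full universe of areas."""
    frame = pd.read_csv(path, comment="#", dtype=str)
    edges = list(frame.itertuples(index=False, name=None))
    if area_ids is None:
        area_ids = sorted({a for e in edges for a in e})
    return AreaLattice.from_edges(list(area_ids), edges)


def write_weights_csv(weights: WeightMatrix, path, seed=None, cfg_hash="-") -> None:
    frame = pd.DataFrame(weights.to_records(), columns=["area_i", "area_j", "weight"])
    write_table(frame, path, seed, cfg_hash)


# ---------------------------------------------------------------------------
# polygons


def write_geojson_polygons(polygons: Mapping[str, object], path,
                           properties: Mapping[str, Mapping] | None = None,
                           id_property: str = "area_id") -> None:
    feats = []
    for aid, geom in polygons.items():
        props = {id_property: aid}
        if properties and aid in properties:
            props.update(properties[aid])
        feats.append({"type": "Feature", "properties": props,
                      "geometry": geom_mapping(geom)})
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson_polygons(path, id_property: str = "area_id") -> dict[str, object]:
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    out = {}
    for feat in gj["features"]:
        aid = str(feat["properties"][id_property])
        out[aid] = geom_shape(feat["geometry"])
    return out


# ---------------------------------------------------------------------------
# stations


def write_stations(stations: Sequence[StationRecord], meta_path, daily_path,
                   year: int = 2016, seed=None, cfg_hash="-") -> None:
    """Station metadata CSV + long-format daily CSV (empty cell = missing)."""
    meta = pd.DataFrame(
        [{"station_id": s.station_id, "lon": s.lon, "lat": s.lat,
          "altitude_m": s.altitude_m, "variable": s.variable} for s in stations])
    write_table(meta, meta_path, seed, cfg_hash)
    rows = []
    for s in stations:
        dates = pd.date_range(f"{year}-01-01", periods=len(s.values), freq="D")
        rows.append(pd.DataFrame({"station_id": s.station_id,
                                  "date": dates.strftime("%Y-%m-%d"),
                                  "variable": s.variable, "value": s.values}))
    write_table(pd.concat(rows, ignore_index=True), daily_path, seed, cfg_hash)


def read_stations(meta_path, daily_path) -> list[StationRecord]:
    meta = read_table(meta_path)
    daily = read_table(daily_path)
    records = []
    for _, m in meta.iterrows():
        sub = daily[(daily["station_id"] == m["station_id"])
                    & (daily["variable"] == m["variable"])].sort_values("date")
        records.append(StationRecord(str(m["station_id"]), float(m["lon"]),
                                     float(m["lat"]), float(m["altitude_m"]),
                                     str(m["variable"]),
                                     sub["value"].to_numpy(dtype=float)))
    return records


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Paths, outcomes, covariates, spec overrides and the master seed."""

    paths: dict[str, str] = field(default_factory=dict)
    outcomes: list[str] = field(default_factory=lambda: ["deaths"])
    covariates: list[str] = field(default_factory=list)
    spec_overrides: dict = field(default_factory=dict)
    master_seed: int = 0
    outdir: str = "arealrisk_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> list[str]:
        """Return every problem found (missing paths...), not just the first."""
        errors = []
        for key, p in self.paths.items():
            if not Path(p).exists():
                errors.append(f"paths.{key}: {p} does not exist")
        if not self.outcomes:
            errors.append("no outcomes specified")
        return errors

    def hash(self) -> str:
        return config_hash({
            "paths": self.paths, "outcomes": self.outcomes,
            "covariates": self.covariates, "spec_overrides": self.spec_overrides,
            "master_seed": self.master_seed})


def write_manifest(paths: Sequence[Path], out_path, seed, cfg_hash) -> None:
    """JSON manifest with SHA-256 of each artifact."""
    entries = {}
    for p in paths:
        p = Path(p)
        entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump({"seed": seed, "config": cfg_hash, "files": entries}, fh, indent=1)


def write_json(obj, path, seed=None, cfg_hash="-") -> None:
    payload = {"seed": seed, "config": cfg_hash, **obj}

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, default=default)
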