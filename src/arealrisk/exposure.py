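"""Monitoring-station exposure assignment.

Environmental exposure (minimum temperature, pollutant concentrations) is
observed at a sparse network of monitors, while the analysis units are areal.
The pipeline here is the standard nearest-monitor design: filter unusable
stations (high altitude, excessive missingness), average each station's daily
series to an annual mean, then give every area the value of the station
nearest its centroid (great-circle distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StationRecord",
    "ExposureAssignment",
    "NoUsableStationsError",
    "filter_stations",
    "annual_mean",
    "assign_nearest",
    "distance_summary",
    "haversine_km",
]

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


class NoUsableStationsError(ValueError):
    """All stations were excluded by the filters."""


@dataclass
class StationRecord:
    """One monitor's metadata and one calendar year of daily values.

    Missing days are NaN in ``values`` — never a magic number. ``values``
    must have calendar-year length (365 or 366).
    """

    station_id: str
    lon: float
    lat: float
    altitude_m: float
    variable: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) not in (365, 366):
            raise ValueError(
                f"station {self.station_id!r}: daily series must cover a "
                f"calendar year (365/366 days), got {self.values.shape}"
            )
        if not np.isfinite(self.altitude_m):
            raise ValueError(f"station {self.station_id!r}: altitude not finite")

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())


def filter_stations(
    stations: Sequence[StationRecord],
    max_altitude_m: float = 200.0,
    max_missing_fraction: float = 0.25,
) -> list[StationRecord]:
    """Drop stations above ``max_altitude_m`` or with too many missing days.

    Thresholds are exclusive ("higher than", "exceeding"): a station exactly
    at 200 m or exactly 25% missing is retained. Exclusion reasons are
    logged per station. Raises :class:`NoUsableStationsError` if nothing
    survives.
    """
    if max_altitude_m <= 0 or max_missing_fraction <= 0:
        raise ValueError("thresholds must be positive")
    kept = []
    for s in stations:
        reasons = []
        if s.altitude_m > max_altitude_m:
            reasons.append(f"altitude {s.altitude_m:g} m > {max_altitude_m:g} m")
        if s.missing_fraction > max_missing_fraction:
            reasons.append(
                f"missing fraction {s.missing_fraction:.3f} > {max_missing_fraction:g}"
            )
        if reasons:
            log.info("excluding station %s: %s", s.station_id, "; ".join(reasons))
        else:
            kept.append(s)
    if not kept:
        raise NoUsableStationsError("no usable stations after filtering")
    return kept


def annual_mean(record: StationRecord) -> float:
    """Arithmetic mean over the non-missing days of the year."""
    vals = record.values
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError(f"station {record.station_id!r}: all days missing")
    return float(vals[ok].mean())


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a 6371-km sphere. Broadcasts."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class ExposureAssignment:
    """Per-area nearest-station assignment for one exposure variable."""

    variable: str
    frame: pd.DataFrame  # columns: area_id, station_id, distance_km, annual_mean

    def __post_init__(self):
        required = {"area_id", "station_id", "distance_km", "annual_mean"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"assignment frame missing columns {required - set(self.frame.columns)}")


def assign_nearest(
    centroids: Mapping[str, tuple[float, float]],
    stations: Sequence[StationRecord],
    metric: str = "haversine",
) -> ExposureAssignment:
    """Assign each area the annual mean of its nearest station.

    Distance is great-circle on (lon, lat) degrees by default; planar
    Euclidean is available for projected coordinates. Exact distance ties
    break toward the lexicographically smallest station id.
    """
    if not stations:
        raise NoUsableStationsError("no stations to assign from")
    variables = {s.variable for s in stations}
    if len(variables) != 1:
        raise ValueError(f"stations mix variables: {sorted(variables)}")
    order = np.argsort([s.station_id for s in stations], kind="stable")
    stations = [stations[i] for i in order]

    area_ids = list(centroids)
    pts = np.array([centroids[a] for a in area_ids], dtype=float)
    if not np.isfinite(pts).all():
        raise ValueError("non-finite centroid coordinates")
    slon = np.array([s.lon for s in stations])
    slat = np.array([s.lat for s in stations])
    if metric == "haversine":
        D = haversine_km(pts[:, [0]], pts[:, [1]], slon[None, :], slat[None, :])
    elif metric == "euclidean":
        D = np.hypot(pts[:, [0]] - slon[None, :], pts[:, [1]] - slat[None, :])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # argmin returns the first minimal index; stations are sorted by id, so
    # exact ties resolve lexicographically.
    nearest = D.argmin(axis=1)
    means = np.array([annual_mean(s) for s in stations])
    frame = pd.DataFrame(
        {
            "area_id": area_ids,
            "station_id": [stations[k].station_id for k in nearest],
            "distance_km": D[np.arange(len(area_ids)), nearest],
            "annual_mean": means[nearest],
        }
    )
    return ExposureAssignment(next(iter(variables)), frame)


def distance_summary(assignment: ExposureAssignment) -> dict[str, float]:
    """Median / min / max of area-to-assigned-station distances in km."""
    d = assignment.frame["distance_km"].to_numpy()
    if len(d) == 0:
        raise ValueError("empty assignment")
    return {"median": float(np.median(d)), "min": float(d.min()), "max": float(d.max())}
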