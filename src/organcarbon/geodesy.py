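"""Great-circle geometry and record-to-coordinate resolution.

Organ travel distance is the straight-line (great-circle) distance in
statute miles between the centroid of the donor hospital ZIP code and the
centroid of the recipient transplant-center ZIP code, computed with the
haversine formula on a sphere. When the recipient ZIP is missing, the
centroid of the center's "City, ST" address is used as a fallback.

ZIP centroids are supplied as an input gazetteer (e.g., a Census ZCTA
centroid file, or the synthetic gazetteer emitted by the cohort
generator); no ZIP database is embedded here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_EARTH_RADIUS_MILES


@dataclass(frozen=True)
class GeoPoint:
    """A latitude/longitude pair in decimal degrees."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not math.isfinite(self.longitude):
            raise ValueError("longitude must be finite")


class ResolutionError(ValueError):
    """An endpoint of a transplant record could not be placed on the map."""


@dataclass
class ZipGazetteer:
    """Postal-code and city-state centroids.

    ``zip_entries`` maps 5-digit (or synthetic) postal-code strings to
    (lat, lon); ``city_state_entries`` maps "City, ST" strings likewise.
    """

    zip_entries: dict[str, tuple[float, float]] = field(default_factory=dict)
    city_state_entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def add_zip(self, code: str, lat: float, lon: float) -> None:
        self._check(lat, lon)
        self.zip_entries[str(code)] = (float(lat), float(lon))

    def add_city_state(self, key: str, lat: float, lon: float) -> None:
        self._check(lat, lon)
        self.city_state_entries[str(key)] = (float(lat), float(lon))

    @staticmethod
    def _check(lat: float, lon: float) -> None:
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} outside [-180, 180]")

    def zip_point(self, code) -> GeoPoint | None:
        if code is None or (isinstance(code, float) and math.isnan(code)):
            return None
        entry = self.zip_entries.get(str(code))
        return GeoPoint(*entry) if entry is not None else None

    def city_state_point(self, key) -> GeoPoint | None:
        if key is None or (isinstance(key, float) and math.isnan(key)):
            return None
        entry = self.city_state_entries.get(str(key))
        return GeoPoint(*entry) if entry is not None else None

    def to_frame(self) -> pd.DataFrame:
        rows = [("zip", k, lat, lon) for k, (lat, lon) in self.zip_entries.items()]
        rows += [
            ("city_state", k, lat, lon)
            for k, (lat, lon) in self.city_state_entries.items()
        ]
        return pd.DataFrame(rows, columns=["kind", "key", "lat", "lon"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ZipGazetteer":
        gaz = cls()
        for row in frame.itertuples(index=False):
            if row.kind == "zip":
                gaz.add_zip(row.key, row.lat, row.lon)
            elif row.kind == "city_state":
                gaz.add_city_state(row.key, row.lat, row.lon)
            else:
                raise ValueError(f"unknown gazetteer kind {row.kind!r}")
        return gaz

    @classmethod
    def from_csv(cls, path) -> "ZipGazetteer":
        return cls.from_frame(pd.read_csv(path, dtype={"key": str}))


def haversine(
    a: GeoPoint, b: GeoPoint, radius_miles: float = DEFAULT_EARTH_RADIUS_MILES
) -> float:
    """Great-circle distance in miles between two points.

    Uses the haversine formula on a sphere of ``radius_miles`` (default:
    mean Earth radius, 3958.8 mi). Symmetric and non-negative.
    """
    lat1, lon1, lat2, lon2 = map(
        math.radians, (a.latitude, a.longitude, b.latitude, b.longitude)
    )
    h = (
        math.sin((lat2 - lat1) / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * radius_miles * math.asin(min(1.0, math.sqrt(h)))


def haversine_arrays(
    lat1, lon1, lat2, lon2, radius_miles: float = DEFAULT_EARTH_RADIUS_MILES
) -> np.ndarray:
    """Vectorized haversine over arrays of coordinates in degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    h = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * radius_miles * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def destination_point(
    lat: float,
    lon: float,
    bearing: float,
    distance_miles: float,
    radius_miles: float = DEFAULT_EARTH_RADIUS_MILES,
) -> tuple[float, float]:
    """Point reached by travelling ``distance_miles`` from (lat, lon)
    along an initial ``bearing`` (degrees clockwise from north) on the
    sphere. Inverse companion of :func:`haversine`: the great-circle
    distance from the origin to the result equals ``distance_miles``.
    """
    if distance_miles < 0:
        raise ValueError("distance must be >= 0")
    lat1 = math.radians(lat)
    lon1 = math.radians(lon)
    theta = math.radians(bearing)
    delta = distance_miles / radius_miles
    lat2 = math.asin(
        math.sin(lat1) * math.cos(delta)
        + math.cos(lat1) * math.sin(delta) * math.cos(theta)
    )
    lon2 = lon1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(lat1),
        math.cos(delta) - math.sin(lat1) * math.sin(lat2),
    )
    lon2 = (lon2 + math.pi) % (2.0 * math.pi) - math.pi
    return math.degrees(lat2), math.degrees(lon2)


def destination_point_arrays(lat, lon, bearing, distance_miles,
                             radius_miles: float = DEFAULT_EARTH_RADIUS_MILES):
    """Vectorized :func:`destination_point` (degrees in, degrees out)."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing, dtype=float))
    delta = np.asarray(distance_miles, dtype=float) / radius_miles
    lat2 = np.arcsin(
        np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(theta)
    )
    lon2 = lon1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    lon2 = (lon2 + np.pi) % (2.0 * np.pi) - np.pi
    return np.degrees(lat2), np.degrees(lon2)


@dataclass(frozen=True)
class ResolvedTrip:
    """One organ movement with both endpoints placed and distance computed."""

    record_id: str
    organ: str
    transplant_date: object
    origin: GeoPoint
    destination: GeoPoint
    distance_miles: float
    resolution_flags: tuple[str, ...] = ()


def resolve_trip(
    record,
    gaz: ZipGazetteer,
    radius_miles: float = DEFAULT_EARTH_RADIUS_MILES,
) -> ResolvedTrip:
    """Place a transplant record's endpoints and compute its distance.

    The donor endpoint comes from the donor ZIP centroid; the recipient
    endpoint from the recipient ZIP centroid, falling back to the
    "City, ST" centroid when the recipient ZIP is missing or unknown
    (flagged ``city_state_fallback``).

    Raises
    ------
    ResolutionError
        If either endpoint cannot be placed. Callers batching many
        records count these and drop the record (see
        :func:`resolve_trips`).
    """
    origin = gaz.zip_point(record.donor_zip)
    if origin is None:
        raise ResolutionError(
            f"{record.record_id}: donor ZIP {record.donor_zip!r} unresolvable"
        )
    flags = ["donor_zip"]
    destination = gaz.zip_point(record.recipient_zip)
    if destination is not None:
        flags.append("recipient_zip")
    else:
        destination = gaz.city_state_point(record.recipient_city_state)
        if destination is None:
            raise ResolutionError(
                f"{record.record_id}: recipient endpoint unresolvable "
                f"(zip={record.recipient_zip!r}, "
                f"city_state={record.recipient_city_state!r})"
            )
        flags.append("city_state_fallback")
    return ResolvedTrip(
        record_id=record.record_id,
        organ=record.organ,
        transplant_date=record.transplant_date,
        origin=origin,
        destination=destination,
        distance_miles=haversine(origin, destination, radius_miles),
        resolution_flags=tuple(flags),
    )


def resolve_trips(
    records,
    gaz: ZipGazetteer,
    radius_miles: float = DEFAULT_EARTH_RADIUS_MILES,
) -> tuple[pd.DataFrame, int]:
    """Resolve a batch of records to a trips table.

    Unresolvable records are dropped and counted rather than aborting the
    run, mirroring how registry analyses handle a handful of bad
    addresses. Returns ``(trips, n_unresolved)`` where ``trips`` has
    columns record_id, organ, transplant_date, distance_miles,
    resolution_flags.
    """
    rows = []
    n_unresolved = 0
    for rec in records:
        try:
            trip = resolve_trip(rec, gaz, radius_miles)
        except ResolutionError:
            n_unresolved += 1
            continue
        rows.append(
            (
                trip.record_id,
                trip.organ,
                trip.transplant_date,
                trip.distance_miles,
                "|".join(trip.resolution_flags),
            )
        )
    trips = pd.DataFrame(
        rows,
        columns=["record_id", "organ", "transplant_date", "distance_miles", "resolution_flags"],
    )
    return trips, n_unresolved
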