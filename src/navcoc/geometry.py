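"""Great-circle geometry on a spherical Earth.

All routes are great circles — the shortest path on the sphere between a
migration's start and end point — and all distances are in kilometres on a
sphere of radius :data:`EARTH_RADIUS_KM`. Cross-track deviations are *signed*:
positive means the point lies to the left of the route's start-to-end
direction of travel. Side persistence is what the downstream AR(1) deviation
model keys on, so the sign convention matters and is fixed here once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "GCRoute",
    "Deviation",
    "DeviationSeries",
    "gc_distance",
    "initial_bearing",
    "destination_point",
    "cross_track_deviation",
    "deviation_series",
]

#: Earth radius used throughout the package (spherical model), km.
EARTH_RADIUS_KM = 6371.0


def _normalize_lon(lon: float) -> float:
    """Wrap a longitude into [-180, 180)."""
    lon = (lon + 180.0) % 360.0 - 180.0
    return lon


@dataclass(frozen=True)
class GeoPoint:
    """A point on the sphere: longitude (degrees east), latitude (degrees north)."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not math.isfinite(self.lon):
            raise ValueError("longitude must be finite")
        object.__setattr__(self, "lon", _normalize_lon(self.lon))


@dataclass(frozen=True)
class GCRoute:
    """A great-circle route from ``start`` to ``end`` (start != end)."""

    start: GeoPoint
    end: GeoPoint
    length_km: float = field(init=False)

    def __post_init__(self) -> None:
        d = gc_distance(self.start, self.end)
        if d == 0.0:
            raise ValueError("degenerate route: start == end")
        object.__setattr__(self, "length_km", d)


@dataclass(frozen=True)
class Deviation:
    """Signed cross-track deviation (km; positive = left of travel direction)."""

    value_km: float
    time_index: int


@dataclass
class DeviationSeries:
    """Signed daily cross-track deviations of one animal from its route.

    ``values_km`` holds one entry per day on the regular time grid; missing
    days are NaN. This is the observation series y_t of the state-space model.
    """

    animal_id: str
    sex: str
    values_km: np.ndarray
    day_index: np.ndarray

    def __post_init__(self) -> None:
        self.values_km = np.asarray(self.values_km, dtype=float)
        self.day_index = np.asarray(self.day_index, dtype=int)
        if self.values_km.shape != self.day_index.shape:
            raise ValueError("values_km and day_index must have equal length")

    def __len__(self) -> int:
        return len(self.values_km)

    @property
    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.values_km)


def _to_rad(p: GeoPoint) -> tuple[float, float]:
    return math.radians(p.lon), math.radians(p.lat)


def gc_distance(p1: GeoPoint, p2: GeoPoint) -> float:
    """Great-circle (haversine) distance in km between two points."""
    lon1, lat1 = _to_rad(p1)
    lon2, lat2 = _to_rad(p2)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    a = min(1.0, max(0.0, a))
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def initial_bearing(p1: GeoPoint, p2: GeoPoint) -> float:
    """Initial bearing (radians, clockwise from north) of the great circle p1 -> p2."""
    lon1, lat1 = _to_rad(p1)
    lon2, lat2 = _to_rad(p2)
    dlon = lon2 - lon1
    y = math.sin(dlon) * math.cos(lat2)
    x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    return math.atan2(y, x)


def destination_point(p: GeoPoint, bearing_rad: float, distance_km: float) -> GeoPoint:
    """Point reached travelling ``distance_km`` along the given initial bearing."""
    lon1, lat1 = _to_rad(p)
    delta = distance_km / EARTH_RADIUS_KM
    lat2 = math.asin(
        math.sin(lat1) * math.cos(delta) + math.cos(lat1) * math.sin(delta) * math.cos(bearing_rad)
    )
    lon2 = lon1 + math.atan2(
        math.sin(bearing_rad) * math.sin(delta) * math.cos(lat1),
        math.cos(delta) - math.sin(lat1) * math.sin(lat2),
    )
    return GeoPoint(math.degrees(lon2), math.degrees(lat2))


def _along_track_fraction(p: GeoPoint, route: GCRoute) -> float:
    """Fraction of the route length at which p's foot point falls (may be <0 or >1)."""
    d13 = gc_distance(route.start, p) / EARTH_RADIUS_KM
    theta13 = initial_bearing(route.start, p)
    theta12 = initial_bearing(route.start, route.end)
    dxt = math.asin(
        min(1.0, max(-1.0, math.sin(d13) * math.sin(theta13 - theta12)))
    )
    # signed along-track angular distance from start to the foot point
    cos_dxt = math.cos(dxt)
    if cos_dxt == 0.0:
        return math.nan
    dat = math.acos(min(1.0, max(-1.0, math.cos(d13) / cos_dxt)))
    if math.cos(theta13 - theta12) < 0.0:
        dat = -dat
    return dat * EARTH_RADIUS_KM / route.length_km


def cross_track_deviation(
    p: GeoPoint, route: GCRoute, time_index: int = 0, clamp: bool = False
) -> Deviation:
    """Signed great-circle distance from ``p`` to the route (positive = left).

    By default the distance is to the route's *full* great circle (the route is
    a line of reference, not a segment); with ``clamp=True`` a foot point
    falling outside the start-end arc is replaced by the nearer endpoint, whose
    distance is reported with the same side sign.
    """
    d13 = gc_distance(route.start, p) / EARTH_RADIUS_KM
    theta13 = initial_bearing(route.start, p)
    theta12 = initial_bearing(route.start, route.end)
    s = math.sin(d13) * math.sin(theta13 - theta12)
    dxt = math.asin(min(1.0, max(-1.0, s)))
    if abs(abs(dxt) - math.pi / 2.0) < 1e-12:
        raise ValueError("point is a pole of the route's great circle; cross-track undefined")
    # standard formula is positive to the RIGHT of travel; flip for left-positive
    value = -dxt * EARTH_RADIUS_KM
    if clamp:
        frac = _along_track_fraction(p, route)
        if frac < 0.0 or frac > 1.0:
            endpoint = route.start if frac < 0.0 else route.end
            value = math.copysign(gc_distance(p, endpoint), value)
    return Deviation(value_km=value, time_index=time_index)


def deviation_series(
    track: "RegularizedTrack | Sequence[tuple[float, float]]",
    route: GCRoute,
    clamp: bool = False,
) -> DeviationSeries:
    """Signed cross-track deviation of every regularized location from ``route``.

    Accepts either a :class:`~navcoc.preprocess.RegularizedTrack` or a bare
    sequence of (lon, lat) pairs (NaN coordinates mark missing days). Order is
    preserved; missing days yield NaN deviations.
    """
    animal_id, sex = "", "unknown"
    if hasattr(track, "locations"):
        animal_id, sex = track.animal_id, track.sex
        coords = [(loc.lon, loc.lat) for loc in track.locations]
        days = np.array([loc.day_index for loc in track.locations], dtype=int)
    else:
        coords = list(track)
        days = np.arange(len(coords))
    if len(coords) == 0:
        raise ValueError("empty track")
    values = np.full(len(coords), np.nan)
    for i, (lon, lat) in enumerate(coords):
        if not (math.isfinite(lon) and math.isfinite(lat)):
            continue
        values[i] = cross_track_deviation(GeoPoint(lon, lat), route, i, clamp=clamp).value_km
    return DeviationSeries(animal_id=animal_id, sex=sex, values_km=values, day_index=days)
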