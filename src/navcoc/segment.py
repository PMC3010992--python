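"""Migration-phase segmentation of regularized tracks.

Migration onset is taken as the peak of robustly smoothed daily travel rates
(excluding the first post-tagging week, where elevated speeds are a handling
artefact rather than departure); migration end as the first persistent
reversal in the direction of smoothed longitude change, the signature of the
localized foraging/breeding-area behaviour that follows a directed southward
migration. Tracks can also be split where they cross a current boundary (for
the drift-compensation test), and deviation series can be trimmed at both
ends (tied-down random-walk sensitivity check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .geometry import DeviationSeries, GeoPoint
from .preprocess import RegularizedTrack

__all__ = [
    "SegmentBounds",
    "BoundaryPolyline",
    "robust_smooth",
    "detect_migration_start",
    "detect_migration_end",
    "detect_bounds",
    "split_at_boundary",
    "trim_edges",
]

KM_PER_DEG_LAT = 111.19492664455873  # 2*pi*R/360 with R = 6371 km


@dataclass(frozen=True)
class SegmentBounds:
    start_index: int
    end_index: int
    method: str = "auto"  # {auto, manual}

    def __post_init__(self) -> None:
        if not (0 <= self.start_index < self.end_index):
            raise ValueError("require 0 <= start_index < end_index")


@dataclass
class BoundaryPolyline:
    """Current boundary as an ordered west-to-east polyline with a half-width band (km)."""

    vertices: list[GeoPoint]
    band_km: float = 0.0

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("boundary polyline needs >= 2 vertices")
        if self.band_km < 0:
            raise ValueError("band_km must be nonnegative")

    def latitude_at(self, lon: float) -> float:
        """Piecewise-linear boundary latitude at a longitude (extrapolates flat)."""
        lons = np.array([v.lon for v in self.vertices])
        lats = np.array([v.lat for v in self.vertices])
        order = np.argsort(lons)
        return float(np.interp(lon, lons[order], lats[order]))


def robust_smooth(series: np.ndarray, window_days: int = 7) -> np.ndarray:
    """Running median of width ``window_days`` followed by one Hanning pass.

    Endpoints of the output are copied from the input. The running median
    absorbs isolated spikes; the Hanning pass (weights 1/4, 1/2, 1/4) removes
    the staircase the median leaves behind.
    """
    x = np.asarray(series, dtype=float)
    if window_days < 3 or window_days % 2 == 0:
        raise ValueError("window_days must be odd and >= 3")
    if len(x) < window_days:
        raise ValueError(f"series length {len(x)} shorter than window {window_days}")
    med = median_filter(x, size=window_days, mode="nearest")
    sm = med.copy()
    sm[1:-1] = 0.25 * med[:-2] + 0.5 * med[1:-1] + 0.25 * med[2:]
    sm[0] = x[0]
    sm[-1] = x[-1]
    return sm


def detect_migration_start(
    rates: np.ndarray, exclude_days: int = 7, window_days: int = 7
) -> int:
    """Index of the peak smoothed travel rate, ignoring the first ``exclude_days``."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) <= exclude_days + window_days:
        raise ValueError("rate series too short for start detection")
    sm = robust_smooth(rates, window_days)
    return int(exclude_days + np.nanargmax(sm[exclude_days:]))


def detect_migration_end(
    longitudes: np.ndarray,
    start: int,
    persist_days: int = 5,
    window_days: int = 7,
) -> int:
    """First persistent reversal of the smoothed longitude-change sign after ``start``.

    The prevailing direction is the sign of the median smoothed day-to-day
    longitude change over the post-start migration leg; the end point is the
    first index after ``start`` where the opposite sign holds for at least
    ``persist_days`` consecutive days. Falls back to the last index (with a
    warning) when no such reversal exists.
    """
    lons = np.asarray(longitudes, dtype=float)
    last = len(lons) - 1
    if start >= len(lons) - persist_days:
        raise ValueError("start too close to end of series")
    sm = robust_smooth(lons, window_days)
    d = np.diff(sm)  # d[i] = change from day i to i+1
    baseline = np.sign(np.nanmedian(d[start : min(start + 14, len(d))]))
    if baseline == 0:
        warnings.warn("no prevailing longitude direction after start; using last index")
        return last
    opposite = np.sign(d) == -baseline
    for i in range(start + 1, len(d) - persist_days + 1):
        if opposite[i : i + persist_days].all():
            return i
    warnings.warn("no persistent longitude reversal found; migration end set to last index")
    return last


def detect_bounds(
    track: RegularizedTrack,
    exclude_days: int = 7,
    persist_days: int = 5,
    window_days: int = 7,
) -> SegmentBounds:
    """Detect migration start and end day indices for one regularized track."""
    from .preprocess import travel_rates

    rates = travel_rates(track)
    start = detect_migration_start(rates, exclude_days, window_days)
    lons = track.coords()[:, 0]
    # rates[i] covers movement into day i+1; the peak maps to that arrival day
    start_day = min(start + 1, len(lons) - persist_days - 1)
    end = detect_migration_end(lons, start_day, persist_days, window_days)
    return SegmentBounds(start_day, end, method="auto")


def split_at_boundary(
    track: RegularizedTrack, boundary: BoundaryPolyline
) -> tuple[RegularizedTrack, RegularizedTrack]:
    """Split a track at its crossing to the south side of a boundary polyline.

    ``after`` starts at the first location south of the boundary that is never
    later followed by a return north of boundary + band; ``before`` holds
    everything earlier. The caller defines a fresh great-circle route from
    ``after``'s first location.
    """
    coords = track.coords()
    band_deg = boundary.band_km / KM_PER_DEG_LAT
    n = len(coords)
    south = np.zeros(n, dtype=bool)
    north_of_band = np.zeros(n, dtype=bool)
    for i, (lon, lat) in enumerate(coords):
        if not np.isfinite(lat):
            continue
        blat = boundary.latitude_at(lon)
        south[i] = lat < blat
        north_of_band[i] = lat > blat + band_deg
    ever_north_later = np.zeros(n, dtype=bool)
    seen = False
    for i in range(n - 1, -1, -1):
        ever_north_later[i] = seen
        if north_of_band[i]:
            seen = True
    split = None
    started_north = False
    for i in range(n):
        if np.isfinite(coords[i, 1]) and not south[i]:
            started_north = True
        if south[i] and started_north and not ever_north_later[i]:
            split = i
            break
    if split is None:
        raise ValueError(f"track {track.animal_id} never crosses the boundary southward")
    before = RegularizedTrack(
        track.animal_id, track.sex, track.window_start, track.step_hours, track.locations[:split]
    )
    after = RegularizedTrack(
        track.animal_id, track.sex, track.window_start, track.step_hours, track.locations[split:]
    )
    return before, after


def trim_edges(series: DeviationSeries, frac: float = 0.025) -> DeviationSeries:
    """Drop floor(frac * T) deviations from each end of the series."""
    if not (0 <= frac < 0.5):
        raise ValueError("frac must be in [0, 0.5)")
    T = len(series)
    k = int(np.floor(frac * T))
    if k == 0:
        return series
    return DeviationSeries(
        animal_id=series.animal_id,
        sex=series.sex,
        values_km=series.values_km[k : T - k],
        day_index=series.day_index[k : T - k],
    )
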