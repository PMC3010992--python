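"""Regularization of irregular satellite-tag tracks to one robust daily location.

Argos-class tags report several fixes per day, contaminated by occasional
gross outliers. The pipeline collapses each 24 h window to a single robust
two-dimensional location: the Minimum Covariance Determinant (MCD) location
when a window holds at least four fixes, and the coordinate-wise median when
it holds one to three (the MCD is not computable there). Empty windows are
kept as explicit missing days so the downstream state-space model can let the
latent state evolve across gaps.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import MinCovDet

from .geometry import gc_distance, GeoPoint

__all__ = [
    "RawFix",
    "RawTrack",
    "DailyLocation",
    "RegularizedTrack",
    "partition_windows",
    "mcd_location",
    "median_location",
    "regularize",
    "travel_rates",
    "TrackRegularizer",
    "read_tracks",
    "write_regularized",
    "read_regularized",
]

#: Exhaustive MCD subset search is exact and affordable up to this window size.
EXHAUSTIVE_MCD_MAX_N = 12


@dataclass(frozen=True)
class RawFix:
    timestamp: datetime
    lon: float
    lat: float
    loc_class: Optional[str] = None  # Argos quality code; carried, not used


@dataclass
class RawTrack:
    animal_id: str
    sex: str  # {male, female, unknown}
    fixes: list[RawFix]

    def __post_init__(self) -> None:
        if len(self.fixes) < 2:
            raise ValueError(f"track {self.animal_id}: need at least 2 fixes")
        times = [f.timestamp for f in self.fixes]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            self.fixes = sorted(self.fixes, key=lambda f: f.timestamp)


@dataclass(frozen=True)
class DailyLocation:
    day_index: int
    lon: float
    lat: float
    n_fixes: int
    estimator: str  # {mcd, median, missing}
    date: Optional[datetime] = None


@dataclass
class RegularizedTrack:
    """One location per time window, equally spaced; missing windows flagged."""

    animal_id: str
    sex: str
    window_start: datetime
    step_hours: float
    locations: list[DailyLocation]

    def __len__(self) -> int:
        return len(self.locations)

    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat); NaN rows where missing."""
        return np.array([(l.lon, l.lat) for l in self.locations], dtype=float)


def partition_windows(track: RawTrack, step_hours: float = 24.0) -> list[list[RawFix]]:
    """Assign fixes to half-open windows [t0 + k*step, t0 + (k+1)*step).

    The anchor t0 is the first fix's timestamp. Empty interior windows are
    retained as empty groups so day indices stay on a regular grid.
    """
    if step_hours <= 0:
        raise ValueError("step_hours must be positive")
    t0 = track.fixes[0].timestamp
    step = timedelta(hours=step_hours)
    n_windows = int((track.fixes[-1].timestamp - t0) / step) + 1
    groups: list[list[RawFix]] = [[] for _ in range(n_windows)]
    for fix in track.fixes:
        k = int((fix.timestamp - t0) / step)
        groups[k].append(fix)
    return groups


def median_location(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Coordinate-wise median of (lon, lat) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("median_location: empty input")
    return float(np.median(pts[:, 0])), float(np.median(pts[:, 1]))


def default_mcd_subset_size(n: int) -> int:
    """Max-breakdown MCD subset size for 2-D data: floor((n + 3) / 2)."""
    return (n + 3) // 2


def _exhaustive_mcd(pts: np.ndarray, h: int) -> np.ndarray:
    best_det = math.inf
    best_mean = None
    n = len(pts)
    for idx in itertools.combinations(range(n), h):
        sub = pts[list(idx)]
        cov = np.cov(sub, rowvar=False, bias=False)
        det = float(np.linalg.det(cov))
        if det < best_det - 1e-15 or best_mean is None:
            best_det = det
            best_mean = sub.mean(axis=0)
    return best_mean


def mcd_location(
    points: Sequence[tuple[float, float]], h: Optional[int] = None
) -> tuple[float, float]:
    """MCD robust location: mean of the h-subset with minimal covariance determinant.

    Exhaustive over all C(n, h) subsets for n <= 12; FAST-MCD (scikit-learn,
    raw estimate) beyond that. Robust to up to n - h outlying fixes.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 4:
        raise ValueError("mcd_location requires n >= 4; use median_location")
    if h is None:
        h = default_mcd_subset_size(n)
    if not (2 <= h <= n):
        raise ValueError(f"subset size h={h} outside [2, {n}]")
    if n <= EXHAUSTIVE_MCD_MAX_N:
        mean = _exhaustive_mcd(pts, h)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                est = MinCovDet(support_fraction=h / n, random_state=0).fit(pts)
                mean = est.raw_location_
            except ValueError:  # degenerate (e.g. collinear) windows
                mean = pts.mean(axis=0)
    return float(mean[0]), float(mean[1])


def regularize(
    track: RawTrack, step_hours: float = 24.0, h: Optional[int] = None
) -> RegularizedTrack:
    """Collapse a raw track to one robust location per ``step_hours`` window.

    Windows with >= 4 fixes use the MCD location, 1-3 fixes the coordinate-wise
    median, and empty windows are flagged missing (NaN coordinates).
    """
    groups = partition_windows(track, step_hours)
    if len(groups) < 1:
        raise ValueError("track shorter than one window")
    t0 = track.fixes[0].timestamp
    step = timedelta(hours=step_hours)
    locations: list[DailyLocation] = []
    for k, group in enumerate(groups):
        date = t0 + k * step
        if len(group) == 0:
            locations.append(DailyLocation(k, math.nan, math.nan, 0, "missing", date))
            continue
        pts = [(f.lon, f.lat) for f in group]
        if len(group) >= 4:
            lon, lat = mcd_location(pts, h)
            est = "mcd"
        else:
            lon, lat = median_location(pts)
            est = "median"
        locations.append(DailyLocation(k, lon, lat, len(group), est, date))
    return RegularizedTrack(track.animal_id, track.sex, t0, step_hours, locations)


def travel_rates(track: RegularizedTrack) -> np.ndarray:
    """Per-day travel rates (km/day) between consecutive non-missing locations.

    Rate i is the great-circle distance from non-missing location i to
    non-missing location i+1 divided by the day gap between them; the array has
    one entry per consecutive pair of non-missing locations.
    """
    present = [l for l in track.locations if l.estimator != "missing"]
    if len(present) < 2:
        raise ValueError("need at least 2 non-missing locations")
    rates = np.empty(len(present) - 1)
    step_days = track.step_hours / 24.0
    for i in range(len(present) - 1):
        a, b = present[i], present[i + 1]
        d = gc_distance(GeoPoint(a.lon, a.lat), GeoPoint(b.lon, b.lat))
        rates[i] = d / ((b.day_index - a.day_index) * step_days)
    return rates


class TrackRegularizer(BaseEstimator, TransformerMixin):
    """Transformer collapsing raw tracks to equally spaced daily locations.

    Parameters
    ----------
    step_hours : float, default 24
        Window length; the regular time step of the output.
    h : int or None
        MCD subset size; ``None`` uses the max-breakdown floor((n+3)/2).
    """

    def __init__(self, step_hours: float = 24.0, h: Optional[int] = None):
        self.step_hours = step_hours
        self.h = h

    def fit(self, X: Sequence[RawTrack], y=None):
        self.n_tracks_ = len(X)
        return self

    def transform(self, X: Sequence[RawTrack]) -> list[RegularizedTrack]:
        return [regularize(t, self.step_hours, self.h) for t in X]


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_tracks(
    path,
    id_col: str = "animal_id",
    sex_col: str = "sex",
    time_col: str = "timestamp",
    lon_col: str = "lon",
    lat_col: str = "lat",
    class_col: Optional[str] = "loc_class",
    sep: str = ",",
) -> list[RawTrack]:
    """Read raw fixes from a delimited file (ISO-8601 timestamps), one RawTrack per animal."""
    df = pd.read_csv(path, sep=sep)
    if class_col is not None and class_col not in df.columns:
        class_col = None
    tracks = []
    for animal_id, sub in df.groupby(id_col, sort=False):
        sex = str(sub[sex_col].iloc[0]) if sex_col in sub.columns else "unknown"
        fixes = [
            RawFix(
                timestamp=pd.Timestamp(row[time_col]).to_pydatetime(),
                lon=float(row[lon_col]),
                lat=float(row[lat_col]),
                loc_class=str(row[class_col]) if class_col else None,
            )
            for _, row in sub.iterrows()
        ]
        tracks.append(RawTrack(str(animal_id), sex, fixes))
    return tracks


def write_regularized(tracks: Iterable[RegularizedTrack], path) -> None:
    rows = []
    for t in tracks:
        for l in t.locations:
            rows.append(
                dict(
                    animal_id=t.animal_id,
                    sex=t.sex,
                    day_index=l.day_index,
                    date=l.date.isoformat() if l.date else "",
                    lon=l.lon,
                    lat=l.lat,
                    n_fixes=l.n_fixes,
                    estimator=l.estimator,
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_regularized(path) -> list[RegularizedTrack]:
    df = pd.read_csv(path)
    tracks = []
    for animal_id, sub in df.groupby("animal_id", sort=False):
        sub = sub.sort_values("day_index")
        locs = [
            DailyLocation(
                int(r.day_index),
                float(r.lon),
                float(r.lat),
                int(r.n_fixes),
                str(r.estimator),
                pd.Timestamp(r.date).to_pydatetime() if isinstance(r.date, str) and r.date else None,
            )
            for r in sub.itertuples()
        ]
        t0 = locs[0].date or datetime(2000, 1, 1)
        tracks.append(RegularizedTrack(str(animal_id), str(sub["sex"].iloc[0]), t0, 24.0, locs))
    return tracks
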