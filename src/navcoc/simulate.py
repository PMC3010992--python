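"""Synthetic deviation series and Argos-like raw tracks with known truth.

The generator emulates the features of the study system the pipeline is
built for: roughly three-month southward migrations along a great circle
(Nova Scotia to the Caribbean by default), several satellite fixes per day
with occasional gross position outliers, signed cross-track deviations that
follow a high-autocorrelation AR(1) with heavy-tailed (t) shocks, pre- and
post-migration dwell phases with direction churn, group structure of two
sexes with seven individuals each, and an optional mid-track eastward drift
event (a current crossing) after which the animal re-aims at its destination
along a fresh great circle.

Every generator is reproducible bit-for-bit given its seed, and returns the
ground truth needed to score each pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    DeviationSeries,
    GCRoute,
    GeoPoint,
    destination_point,
    initial_bearing,
)
from .preprocess import RawFix, RawTrack

__all__ = [
    "SimulationSpec",
    "simulate_deviations",
    "simulate_population",
    "simulate_argos_track",
    "gc_point_at_fraction",
]

KM_PER_DEG = 111.19492664455873


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic population.

    Defaults mirror the study design the pipeline targets: 7 animals per
    sex, ~90-day migrations, deviation autocorrelation gamma in
    [0.95, 0.99], circles of confusion of 60-150 km, t(4) process shocks and
    ~2 km measurement noise. Per-animal (gamma_j, sigma_j) are drawn from
    hyper-distribution truth rejected into ``gamma_range`` x ``coc_range``
    (the default), given explicitly, or (``hyper=None``) drawn uniformly
    from those ranges.
    """

    n_per_group: int = 7
    group_names: tuple[str, ...] = ("female", "male")
    T: int = 90
    gamma: Optional[Sequence[float]] = None
    sigma: Optional[Sequence[float]] = None
    # hyper truth: gamma_j = 2 Beta(a, b) - 1, sigma_j ~ |N(theta, tau^2)|,
    # with draws truncated to gamma_range x coc_range (the study conditions)
    hyper: Optional[dict] = field(
        default_factory=lambda: dict(a=581.0, b=8.9, theta=25.0, tau=6.0)
    )
    gamma_range: tuple[float, float] = (0.95, 0.99)
    coc_range: tuple[float, float] = (60.0, 150.0)
    nu: float = 4.0
    sigma_eps: float = 2.0
    # raw-track mechanics
    fixes_per_day: float = 6.0
    fix_noise_km: float = 1.5
    outlier_frac: float = 0.05
    outlier_km: float = 500.0
    dwell_pre: int = 10
    dwell_post: int = 15
    dwell_step_km: float = 8.0
    # departure burst: travel rate elevated by this factor at migration onset,
    # decaying over ~departure_decay days (the peak the start detector keys on)
    departure_boost: float = 0.8
    departure_decay: float = 4.0
    route_start: tuple[float, float] = (-63.0, 44.0)  # (lon, lat) off Nova Scotia
    route_end: tuple[float, float] = (-57.0, 13.0)  # eastern Caribbean
    # persistent westward drift of the post-migration dwell (km/day): the
    # localized foraging phase rides prevailing currents, reversing the
    # migration's eastward longitude trend — the signal the end detector uses
    dwell_post_drift_km_day: float = -12.0
    drift_day: Optional[int] = None  # migration day the eastward drift begins
    drift_km: float = 0.0
    drift_len: int = 5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.T < 10:
            raise ValueError("T must be >= 10")
        if not (0.0 <= self.outlier_frac < 1.0):
            raise ValueError("outlier_frac must be in [0, 1)")
        for name in ("sigma_eps", "fix_noise_km", "fixes_per_day"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def simulate_deviations(
    gamma: float,
    sigma: float,
    nu: float,
    sigma_eps: float,
    T: int,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one latent deviation path x and its observed series y.

    x_1 comes from the stationary Gaussian approximation — a normal with the
    process's stationary variance, sigma^2 (nu/(nu-2)) / (1 - gamma^2) when
    the t variance exists (plain sigma^2 / (1 - gamma^2) otherwise);
    subsequent shocks are sigma-scaled t(nu) draws (Gaussian when nu is
    infinite); y adds N(0, sigma_eps^2) measurement noise.
    """
    if abs(gamma) >= 1.0:
        raise ValueError("|gamma| must be < 1")
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.empty(T)
    var_fac = nu / (nu - 2.0) if (math.isfinite(nu) and nu > 2.0) else 1.0
    x[0] = (
        rng.normal(0.0, sigma * math.sqrt(var_fac / (1.0 - gamma * gamma)))
        if sigma > 0
        else 0.0
    )
    if math.isinf(nu):
        shocks = rng.normal(0.0, 1.0, T - 1)
    else:
        shocks = rng.standard_t(nu, T - 1)
    for t in range(1, T):
        x[t] = gamma * x[t - 1] + sigma * shocks[t - 1]
    y = x + (rng.normal(0.0, sigma_eps, T) if sigma_eps > 0 else 0.0)
    return x, y


def _draw_params(spec: SimulationSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = spec.n_per_group * len(spec.group_names)
    if spec.gamma is not None and spec.sigma is not None:
        return np.asarray(spec.gamma, float), np.asarray(spec.sigma, float)
    if spec.hyper is not None:
        h = spec.hyper
        gamma = np.empty(n)
        sigma = np.empty(n)
        for i in range(n):
            for _ in range(1000):  # rejection: keep draws inside study ranges
                g = 2.0 * rng.beta(h["a"], h["b"]) - 1.0
                s = abs(rng.normal(h["theta"], h["tau"]))
                coc = s / math.sqrt(max(1.0 - g * g, 1e-12))
                if (
                    spec.gamma_range[0] <= g <= spec.gamma_range[1]
                    and spec.coc_range[0] <= coc <= spec.coc_range[1]
                ):
                    break
            gamma[i], sigma[i] = g, max(s, 1e-3)
        return gamma, sigma
    gamma = rng.uniform(*spec.gamma_range, n)
    coc = rng.uniform(*spec.coc_range, n)
    return gamma, coc * np.sqrt(1.0 - gamma**2)


def simulate_population(spec: SimulationSpec) -> dict:
    """Simulate deviation series for the whole population.

    Returns a dict with per-animal truth (``gamma``, ``sigma``, ``coc_km``,
    ``sex``, ``animal_id``), the latent paths and a list of
    :class:`DeviationSeries`.
    """
    rng = np.random.default_rng(spec.seed)
    gamma, sigma = _draw_params(spec, rng)
    n = len(gamma)
    sexes = [g for g in spec.group_names for _ in range(spec.n_per_group)]
    if len(sexes) != n:
        sexes = (sexes * ((n // max(len(sexes), 1)) + 1))[:n]
    series, xs = [], []
    ids = [f"T{i:02d}" for i in range(n)]
    for i in range(n):
        x, y = simulate_deviations(gamma[i], sigma[i], spec.nu, spec.sigma_eps, spec.T, rng)
        xs.append(x)
        series.append(
            DeviationSeries(
                animal_id=ids[i], sex=sexes[i], values_km=y, day_index=np.arange(spec.T)
            )
        )
    return {
        "animal_id": ids,
        "sex": sexes,
        "gamma": gamma,
        "sigma": sigma,
        "coc_km": gamma * 0.0 + sigma / np.sqrt(1.0 - gamma**2),
        "x": xs,
        "series": series,
    }


def _slerp(p1: GeoPoint, p2: GeoPoint, frac: float) -> GeoPoint:
    """Spherical linear interpolation between two points (frac in [0, 1])."""
    def to_vec(p: GeoPoint) -> np.ndarray:
        lon, lat = math.radians(p.lon), math.radians(p.lat)
        return np.array(
            [math.cos(lat) * math.cos(lon), math.cos(lat) * math.sin(lon), math.sin(lat)]
        )

    v1, v2 = to_vec(p1), to_vec(p2)
    omega = math.acos(min(1.0, max(-1.0, float(np.dot(v1, v2)))))
    if omega < 1e-12:
        return p1
    v = (math.sin((1 - frac) * omega) * v1 + math.sin(frac * omega) * v2) / math.sin(omega)
    lat = math.degrees(math.asin(min(1.0, max(-1.0, v[2]))))
    lon = math.degrees(math.atan2(v[1], v[0]))
    return GeoPoint(lon, lat)


def gc_point_at_fraction(route: GCRoute, frac: float) -> GeoPoint:
    """Point a fraction of the way along a great-circle route."""
    return _slerp(route.start, route.end, frac)


def _offset_left(p: GeoPoint, toward: GeoPoint, offset_km: float) -> GeoPoint:
    """Displace p perpendicular to its bearing toward ``toward``; positive = left."""
    brg = initial_bearing(p, toward)
    return destination_point(p, brg - math.pi / 2.0, offset_km)


def _deg_jitter(p: GeoPoint, dx_km: float, dy_km: float) -> GeoPoint:
    lat = min(89.9, max(-89.9, p.lat + dy_km / KM_PER_DEG))
    lon = p.lon + dx_km / (KM_PER_DEG * math.cos(math.radians(p.lat)))
    return GeoPoint(lon, lat)


def simulate_argos_track(
    spec: SimulationSpec,
    gamma: float,
    sigma: float,
    animal_id: str = "T00",
    sex: str = "unknown",
    seed=None,
) -> tuple[RawTrack, dict]:
    """Simulate a full Argos-like raw track plus ground truth for one animal.

    The daily true position is along-route progress on the great circle plus
    the cross-track AR(1) offset applied perpendicular (left-positive) to the
    route; dwell phases before and after migration are small-step random
    walks with direction churn. Each day receives a Poisson number of fixes
    jittered by Gaussian noise, a fraction of which are replaced by gross
    outliers. An optional drift event displaces the animal eastward over a
    few days, after which it follows a fresh great circle to its destination.

    Returns the raw track and a truth dict (daily true positions, latent
    x_t, migration start/end day, drift crossing day, parameters).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = GeoPoint(*spec.route_start)
    end = GeoPoint(*spec.route_end)
    route = GCRoute(start, end)
    mig_days = spec.T
    x, _ = simulate_deviations(gamma, sigma, spec.nu, spec.sigma_eps, mig_days, rng)

    # --- daily true positions -------------------------------------------
    total_days = spec.dwell_pre + mig_days + spec.dwell_post
    true_pts: list[GeoPoint] = []
    pos = start
    for _ in range(spec.dwell_pre):
        step = rng.normal(0.0, spec.dwell_step_km, 2)
        pos = _deg_jitter(pos, step[0], step[1])
        true_pts.append(pos)
    # departure burst: elevated travel rate at onset decaying over a few days
    day_speed = 1.0 + spec.departure_boost * np.exp(
        -np.arange(mig_days) / max(spec.departure_decay, 1e-9)
    )
    progress = np.cumsum(day_speed) / np.sum(day_speed)
    drift_done = 0.0
    reroute_from: Optional[GeoPoint] = None
    crossing_day = None
    for d in range(mig_days):
        frac = float(progress[d])
        if spec.drift_day is not None and d >= spec.drift_day and drift_done < spec.drift_km:
            # eastward displacement ramp: the current carries the animal
            base = true_pts[-1]
            drift_step = spec.drift_km / max(spec.drift_len, 1)
            drift_done += drift_step
            pos = _deg_jitter(base, drift_step, -spec.dwell_step_km * 0.2)
            if drift_done >= spec.drift_km:
                reroute_from = pos
                crossing_day = spec.dwell_pre + d + 1
                remaining = mig_days - d - 1
        elif reroute_from is not None:
            # re-aim: fresh great circle from the post-drift point
            f = (d - (crossing_day - spec.dwell_pre) + 1) / max(remaining, 1)
            base = _slerp(reroute_from, end, min(f, 1.0))
            pos = _offset_left(base, end, float(x[d])) if base != end else end
        else:
            base = gc_point_at_fraction(route, frac)
            pos = _offset_left(base, end, float(x[d])) if frac < 1.0 else end
        true_pts.append(pos)
    anchor = true_pts[-1]
    for k in range(spec.dwell_post):
        step = rng.normal(0.0, spec.dwell_step_km, 2)
        # churn about a slowly drifting anchor: localized foraging riding
        # the prevailing current
        drifted = _deg_jitter(anchor, spec.dwell_post_drift_km_day * (k + 1), 0.0)
        pos = _deg_jitter(drifted, step[0], step[1])
        true_pts.append(pos)

    # --- fixes ------------------------------------------------------------
    t0 = datetime(2002, 9, 1)
    fixes: list[RawFix] = []
    for d, p in enumerate(true_pts):
        k = rng.poisson(spec.fixes_per_day)
        if d == 0:
            k = max(k, 1)
        hours = np.sort(rng.uniform(0.0, 24.0, k))
        if d == 0:
            # anchor the first fix at hour 0 so that 24 h regularization
            # windows coincide with the generator's day grid (fixes sample
            # the daily position; within-day movement is not represented)
            hours[0] = 0.0
        # the stated fraction of the day's fixes are gross outliers; a fixed
        # per-day count keeps the contamination at the nominal rate rather
        # than letting binomial luck exceed the MCD breakdown point
        n_out = int(round(spec.outlier_frac * k))
        out_idx = set(rng.choice(k, size=n_out, replace=False)) if n_out else set()
        for i, hr in enumerate(hours):
            if i in out_idx:
                mag = spec.outlier_km * rng.uniform(0.5, 1.5)
                ang = rng.uniform(0.0, 2.0 * math.pi)
                fp = _deg_jitter(p, mag * math.cos(ang), mag * math.sin(ang))
            else:
                dx, dy = rng.normal(0.0, spec.fix_noise_km, 2)
                fp = _deg_jitter(p, dx, dy)
            fixes.append(
                RawFix(timestamp=t0 + timedelta(days=d, hours=float(hr)), lon=fp.lon, lat=fp.lat)
            )
    if len(fixes) < 2:  # pathological low fix rate: anchor endpoints
        fixes = [
            RawFix(t0, true_pts[0].lon, true_pts[0].lat),
            RawFix(t0 + timedelta(days=total_days - 1), true_pts[-1].lon, true_pts[-1].lat),
        ]
    track = RawTrack(animal_id=animal_id, sex=sex, fixes=fixes)
    truth = {
        "gamma": gamma,
        "sigma": sigma,
        "coc_km": gamma * 0.0 + sigma / math.sqrt(1.0 - gamma**2),
        "x": x,
        "true_lon": np.array([p.lon for p in true_pts]),
        "true_lat": np.array([p.lat for p in true_pts]),
        "start_day": spec.dwell_pre,
        "end_day": spec.dwell_pre + mig_days - 1,
        "crossing_day": crossing_day,
        "route": route,
        "t0": t0,
    }
    return track, truth
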