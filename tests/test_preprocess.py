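import itertools
from datetime import datetime, timedelta

import numpy as np
import pytest

from navcoc.preprocess import (
    RawFix,
    RawTrack,
    TrackRegularizer,
    default_mcd_subset_size,
    mcd_location,
    median_location,
    partition_windows,
    read_regularized,
    read_tracks,
    regularize,
    travel_rates,
    write_regularized,
)

T0 = datetime(2002, 9, 1)


def make_track(hours, lons, lats, animal_id="A", sex="female"):
    fixes = [
        RawFix(T0 + timedelta(hours=float(h)), float(lon), float(lat))
        for h, lon, lat in zip(hours, lons, lats)
    ]
    return RawTrack(animal_id, sex, fixes)


def exhaustive_mcd_oracle(pts, h):
    """Independent exhaustive search for the minimal-determinant subset mean."""
    best = (np.inf, None)
    for idx in itertools.combinations(range(len(pts)), h):
        sub = np.asarray(pts)[list(idx)]
        det = np.linalg.det(np.cov(sub, rowvar=False))
        if det < best[0]:
            best = (det, sub.mean(axis=0))
    return best[1]


class TestPartitionWindows:
    def test_single_window(self):
        t = make_track([0, 5, 10, 15, 20], np.zeros(5), np.zeros(5))
        groups = partition_windows(t, 24.0)
        assert len(groups) == 1 and len(groups[0]) == 5

    def test_half_open_boundary(self):
        t = make_track([0.0, 23.9, 24.0], np.zeros(3), np.zeros(3))
        groups = partition_windows(t, 24.0)
        assert [len(g) for g in groups] == [2, 1]

    def test_fix_conservation_with_gaps(self, rng):
        hours = np.sort(rng.uniform(0, 24 * 10, 40))
        t = make_track(hours, rng.uniform(-5, 5, 40), rng.uniform(-5, 5, 40))
        groups = partition_windows(t, 24.0)
        assert sum(len(g) for g in groups) == 40
        # empty windows retained in place
        assert len(groups) == int((hours[-1] - hours[0]) // 24) + 1


class TestMedianLocation:
    @pytest.mark.parametrize(
        "pts, expected",
        [
            ([(1, 1)], (1, 1)),
            ([(0, 0), (1, 2), (2, 1)], (1, 1)),
            ([(0, 0), (0, 0), (9, 9)], (0, 0)),
        ],
    )
    def test_examples(self, pts, expected):
        assert median_location(pts) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_location([])


class TestMcdLocation:
    def test_identical_points(self):
        assert mcd_location([(2.0, 3.0)] * 4) == pytest.approx((2.0, 3.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            mcd_location([(0, 0)] * 3)

    def test_outliers_excluded(self, rng):
        pts = [tuple(rng.normal(0, 0.01, 2)) for _ in range(8)] + [(10.0, 10.0)] * 2
        lon, lat = mcd_location(pts, h=7)
        assert abs(lon) < 0.05 and abs(lat) < 0.05

    def test_matches_exhaustive_oracle(self, rng):
        # random windows with planted outliers, all n <= 12
        for _ in range(100):
            n = int(rng.integers(4, 13))
            pts = rng.normal(0, 1, (n, 2))
            n_out = int(rng.integers(0, max(1, n - default_mcd_subset_size(n)) + 1))
            pts[:n_out] += rng.uniform(50, 500, (n_out, 2))
            h = default_mcd_subset_size(n)
            got = mcd_location([tuple(p) for p in pts], h)
            want = exhaustive_mcd_oracle(pts, h)
            assert got == pytest.approx(tuple(want), abs=1e-10)

    def test_translation_equivariance(self, rng):
        pts = rng.normal(0, 1, (8, 2))
        base = np.array(mcd_location([tuple(p) for p in pts]))
        shifted = np.array(mcd_location([tuple(p + [3.5, -2.0]) for p in pts]))
        np.testing.assert_allclose(shifted, base + [3.5, -2.0], atol=1e-10)

    def test_breakdown_resistance(self, rng):
        good = rng.normal(0, 1, (7, 2))
        bad = rng.uniform(1e4, 1e5, (3, 2))
        pts = np.vstack([good, bad])
        lon, lat = mcd_location([tuple(p) for p in pts], h=7)
        assert good[:, 0].min() - 1e-9 <= lon <= good[:, 0].max() + 1e-9
        assert good[:, 1].min() - 1e-9 <= lat <= good[:, 1].max() + 1e-9


class TestRegularize:
    def test_clean_track_all_mcd(self, rng):
        hours, lons, lats = [], [], []
        for d in range(10):
            for k in range(6):
                hours.append(d * 24 + 2 + 3 * k)
                lons.append(-60.0 + 0.01 * rng.normal())
                lats.append(40.0 - 0.3 * d + 0.01 * rng.normal())
        reg = regularize(make_track(hours, lons, lats))
        assert len(reg) == 10
        assert all(l.estimator == "mcd" for l in reg.locations)
        assert [l.day_index for l in reg.locations] == list(range(10))

    def test_sparse_day_uses_median(self):
        hours = [1, 2, 3, 4, 25, 26, 27]  # day 0: 4 fixes, day 1: 3 fixes
        reg = regularize(make_track(hours, np.zeros(7), np.zeros(7)))
        assert reg.locations[0].estimator == "mcd"
        assert reg.locations[1].estimator == "median"

    def test_empty_day_flagged_missing(self):
        hours = [0, 1, 2, 3, 49]  # nothing in day 1
        reg = regularize(make_track(hours, np.zeros(5), np.zeros(5)))
        assert reg.locations[1].estimator == "missing"
        assert np.isnan(reg.locations[1].lon)

    def test_gross_outlier_rejected(self, rng):
        # 5 fixes, one displaced ~500 km (≈4.5 deg)
        hours = [1, 5, 9, 13, 17]
        lons = [0.0, 0.01, -0.01, 0.005, 4.5]
        lats = [0.0, -0.01, 0.01, 0.0, 4.5]
        reg = regularize(make_track(hours, lons, lats))
        loc = reg.locations[0]
        assert abs(loc.lon) < 0.1 and abs(loc.lat) < 0.1  # within 10 km of cluster

    def test_row_count_equals_window_count(self, rng):
        hours = np.sort(rng.uniform(0, 24 * 15, 60))
        t = make_track(hours, rng.uniform(-1, 1, 60), rng.uniform(-1, 1, 60))
        reg = regularize(t)
        assert len(reg) == len(partition_windows(t, 24.0))


class TestTravelRates:
    def test_stationary_track_zero(self):
        hours = [12 + 24 * d for d in range(5)]
        reg = regularize(make_track(hours, np.zeros(5), np.zeros(5)))
        np.testing.assert_allclose(travel_rates(reg), 0.0, atol=1e-9)

    def test_one_degree_south_per_day(self):
        hours = [12 + 24 * d for d in range(6)]
        lats = [40.0 - d for d in range(6)]
        reg = regularize(make_track(hours, [-60.0] * 6, lats))
        np.testing.assert_allclose(travel_rates(reg), 111.195, atol=0.01)

    def test_rates_nonnegative_and_skip_missing(self, rng):
        hours = [1, 25, 97]  # days 0, 1, 4; days 2-3 missing
        reg = regularize(make_track(hours, [0.0, 1.0, 4.0], [0.0, 0.0, 0.0]))
        r = travel_rates(reg)
        assert len(r) == 2
        assert np.all(r >= 0)
        assert r[1] == pytest.approx(111.195, abs=0.1)  # 3 degrees over 3 days


class TestIO:
    def test_roundtrip(self, tmp_path, rng):
        hours = np.sort(rng.uniform(0, 24 * 5, 30))
        t = make_track(hours, rng.uniform(-61, -60, 30), rng.uniform(39, 40, 30))
        reg = [regularize(t)]
        path = tmp_path / "daily.csv"
        write_regularized(reg, path)
        back = read_regularized(path)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].coords(), reg[0].coords())

    def test_read_tracks_groups_by_animal(self, tmp_path):
        path = tmp_path / "fixes.csv"
        path.write_text(
            "animal_id,sex,timestamp,lon,lat\n"
            "A,female,2002-09-01T00:00:00,-60.0,40.0\n"
            "A,female,2002-09-01T06:00:00,-60.1,39.9\n"
            "B,male,2002-09-01T00:00:00,-59.0,41.0\n"
            "B,male,2002-09-02T00:00:00,-59.2,40.5\n"
        )
        tracks = read_tracks(path)
        assert [t.animal_id for t in tracks] == ["A", "B"]
        assert tracks[0].sex == "female" and tracks[1].sex == "male"


def test_track_regularizer_transformer(rng):
    hours = np.sort(rng.uniform(0, 24 * 6, 36))
    tracks = [make_track(hours, rng.uniform(-61, -60, 36), rng.uniform(39, 40, 36))]
    reg = TrackRegularizer(step_hours=24.0).fit(tracks).transform(tracks)
    assert len(reg) == 1 and len(reg[0]) >= 6
    params = TrackRegularizer().get_params()
    assert params == {"step_hours": 24.0, "h": None}
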