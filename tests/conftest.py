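import numpy as np
import pytest

from navcoc.geometry import GCRoute, GeoPoint


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def equatorial_route():
    return GCRoute(GeoPoint(0.0, 0.0), GeoPoint(90.0, 0.0))


def random_route(rng, min_len_km=500.0, max_len_km=6000.0):
    from navcoc.geometry import destination_point

    start = GeoPoint(rng.uniform(-180, 180), rng.uniform(-60, 60))
    end = destination_point(
        start, rng.uniform(0, 2 * np.pi), rng.uniform(min_len_km, max_len_km)
    )
    return GCRoute(start, end)
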