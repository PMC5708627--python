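import dataclasses

import numpy as np
import pytest

from sonickayak import synthetic as syn
from sonickayak.core import GeoFix, TripLog


def make_log(t, lat=None, lon=None, temp_a=None, temp_b=None, **kw):
    """Build a TripLog from plain sequences with sensible defaults."""
    t = np.asarray(t, dtype=float)
    n = len(t)
    if lat is None:
        lat = np.full(n, 50.155)
    if lon is None:
        lon = np.full(n, -5.065)
    if temp_a is None:
        temp_a = np.full(n, 18.0)
    if temp_b is None:
        temp_b = np.asarray(temp_a, dtype=float)
    kw.setdefault("nominal_rate", None)
    return TripLog.from_arrays(t=t, lat=lat, lon=lon,
                               temp_a=temp_a, temp_b=temp_b, **kw)


def eastward_log(n=120, speed_mps=1.0, lat0=50.0, lon0=-5.0, temp=18.0):
    """A 1 Hz track moving due east at a constant ground speed."""
    t = np.arange(n, dtype=float)
    deg_per_m = 1.0 / (np.pi / 180.0 * 6_371_000.0 * np.cos(np.radians(lat0)))
    lon = lon0 + speed_mps * deg_per_m * t
    return make_log(t, lat=np.full(n, lat0), lon=lon, temp_a=np.full(n, temp))


@pytest.fixture
def manifest():
    return syn.FixtureManifest(seed=0)


@pytest.fixture
def short_manifest():
    """A 5-minute deployment for fast end-to-end tests."""
    m = syn.FixtureManifest(seed=0)
    return dataclasses.replace(
        m, track=dataclasses.replace(m.track, duration_s=300.0)
    )


@pytest.fixture
def noiseless_manifest():
    m = syn.FixtureManifest(seed=0)
    return dataclasses.replace(
        m,
        track=dataclasses.replace(m.track, duration_s=600.0),
        field=dataclasses.replace(m.field, noise_sd_c=0.0),
    )
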