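import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from magbird.geodesy import SpeciesTrack, TrackPoint
from magbird.synthetic_data import synthetic_coefficients


def make_track(coords, species="test", start=datetime(2020, 3, 1), hours=24):
    """Build a SpeciesTrack from (lat, lon) pairs, hourly-spaced."""
    pts = [TrackPoint(species, start + timedelta(hours=i * hours), la, lo)
           for i, (la, lo) in enumerate(coords)]
    return SpeciesTrack(species, pts)


@pytest.fixture
def dipole_coeffs():
    """Earth-like axial dipole: g[1,0] = -30000 nT, static."""
    return synthetic_coefficients("dipole", n_max=2, scale_nT=30000.0)


@pytest.fixture
def random_coeffs():
    """Randomized multipole set, degree 8, fixed seed."""
    return synthetic_coefficients("randomized", n_max=8, scale_nT=30000.0, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def equator_track():
    """Three collinear points eastward along the equator."""
    return make_track([(0.0, 0.0), (0.0, 5.0), (0.0, 10.0)])


def random_points(rng, n, lat_range=(-80, 80)):
    """Random (lat, lon) pairs away from the poles."""
    lats = rng.uniform(*lat_range, n)
    lons = rng.uniform(-180, 180, n)
    return np.column_stack([lats, lons])


def great_circle_bearing_oracle(p1, p2, eps=1e-7):
    """Initial bearing via 3-D slerp: independent of the atan2 formula.

    Moves a tiny fraction ``eps`` of the way along the great circle from
    p1 toward p2 (unit-vector interpolation), converts the displacement
    to local east/north components, and reads off the azimuth.
    """
    def unit(lat, lon):
        la, lo = math.radians(lat), math.radians(lon)
        return np.array([math.cos(la) * math.cos(lo),
                         math.cos(la) * math.sin(lo),
                         math.sin(la)])

    a, b = unit(p1.lat_deg, p1.lon_deg), unit(p2.lat_deg, p2.lon_deg)
    omega = math.acos(np.clip(a @ b, -1, 1))
    q = (math.sin((1 - eps) * omega) * a + math.sin(eps * omega) * b) / math.sin(omega)
    la, lo = math.radians(p1.lat_deg), math.radians(p1.lon_deg)
    east = np.array([-math.sin(lo), math.cos(lo), 0.0])
    north = np.array([-math.sin(la) * math.cos(lo),
                      -math.sin(la) * math.sin(lo), math.cos(la)])
    d = q - a
    return math.atan2(d @ east, d @ north) % (2 * math.pi)
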