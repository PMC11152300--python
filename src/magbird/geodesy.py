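"""Spherical geodesy for animal tracks.

Converts ordered (lat, lon, time) fixes into circular direction series.
All geometry is on the unit sphere: central angles and azimuths do not
depend on the radius, and tracking fixes carry no usable altitude.  Angles
are radians internally; degrees appear only in the ``TrackPoint`` fields,
which mirror the usual tracking-CSV columns.

Two notions of "direction change" are supported:

``bearing``
    The forward azimuth (initial great-circle bearing, clockwise from
    geographic north) of each consecutive segment.  This is the default:
    azimuths are well-defined circular variables, one per segment.
``turn_angle``
    The wrapped difference between consecutive segment bearings, i.e. how
    much the animal turned at each interior fix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np

from .errors import InvalidCoordinateError, TooShortTrackError, UndefinedBearingError

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi

#: central angle below which two fixes count as the same location (radians)
COINCIDENT_TOL = 1e-12

#: |latitude| above this (radians) counts as a pole for azimuth purposes
_POLE_TOL = math.pi / 2 - 1e-12


def wrap_2pi(angle):
    """Wrap angle(s) into [0, 2*pi)."""
    return np.mod(angle, TWO_PI)


def wrap_pi(angle):
    """Wrap angle(s) into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(angle), TWO_PI)


def normalize_lon(lon_deg: float) -> float:
    """Normalize a longitude in degrees to [-180, 180).

    Idempotent: values already in range pass through unchanged, so
    writing and re-reading coordinates is bit-exact.
    """
    if -180.0 <= lon_deg < 180.0:
        return float(lon_deg)
    return float(np.mod(np.asarray(lon_deg) + 180.0, 360.0) - 180.0)


@dataclass(frozen=True)
class TrackPoint:
    """One timed fix of one individual/species."""

    species: str
    time: datetime
    lat_deg: float
    lon_deg: float

    def __post_init__(self):
        if not (math.isfinite(self.lat_deg) and math.isfinite(self.lon_deg)):
            raise InvalidCoordinateError(
                f"non-finite coordinates ({self.lat_deg}, {self.lon_deg})")
        if not -90.0 <= self.lat_deg <= 90.0:
            raise InvalidCoordinateError(f"latitude {self.lat_deg} outside [-90, 90]")
        object.__setattr__(self, "lon_deg", normalize_lon(self.lon_deg))

    @property
    def lat_rad(self) -> float:
        return math.radians(self.lat_deg)

    @property
    def lon_rad(self) -> float:
        return math.radians(self.lon_deg)


@dataclass
class SpeciesTrack:
    """Time-ordered fixes for one species."""

    species: str
    points: list[TrackPoint]

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


@dataclass
class DirectionSeries:
    """Circular direction-change series derived from a track.

    ``theta_rad[i]`` is anchored at ``anchor_points[i]`` — the fix where
    the segment (bearing mode) or the turn (turn-angle mode) begins.
    """

    species: str
    theta_rad: np.ndarray
    mode: str
    anchor_points: list[TrackPoint] = field(default_factory=list)
    #: final distinct fix of the track (closes the last segment)
    end_point: TrackPoint | None = None

    def __len__(self) -> int:
        return len(self.theta_rad)


def central_angle(p1: TrackPoint, p2: TrackPoint) -> float:
    """Great-circle central angle between two points, in radians.

    Analytically ``arccos(sin(phi_A) sin(phi_B) + cos(phi_A) cos(phi_B)
    cos(dL))`` (spherical law of cosines); evaluated in the haversine
    form, which is the same quantity but well conditioned at small
    separations — identical points give exactly 0.  The square-root
    argument is clipped to [0, 1] to absorb rounding.
    """
    phi_a, phi_b = p1.lat_rad, p2.lat_rad
    dl = p2.lon_rad - p1.lon_rad
    hav = (math.sin((phi_b - phi_a) / 2.0) ** 2
           + math.cos(phi_a) * math.cos(phi_b) * math.sin(dl / 2.0) ** 2)
    return 2.0 * math.asin(min(1.0, math.sqrt(max(0.0, hav))))


def initial_bearing(p1: TrackPoint, p2: TrackPoint) -> float:
    """Forward azimuth from ``p1`` toward ``p2``, radians in [0, 2*pi).

    Clockwise from geographic north.  The longitude difference is wrapped
    into (-pi, pi] so antimeridian crossings take the short way round.
    Undefined for coincident points and for departure from a pole.
    """
    if central_angle(p1, p2) < COINCIDENT_TOL:
        raise UndefinedBearingError(
            f"coincident points ({p1.lat_deg}, {p1.lon_deg}) and "
            f"({p2.lat_deg}, {p2.lon_deg})")
    phi_a, phi_b = p1.lat_rad, p2.lat_rad
    if abs(phi_a) > _POLE_TOL:
        raise UndefinedBearingError("bearing undefined at a geographic pole")
    dl = float(wrap_pi(p2.lon_rad - p1.lon_rad))
    y = math.sin(dl) * math.cos(phi_b)
    x = (math.cos(phi_a) * math.sin(phi_b)
         - math.sin(phi_a) * math.cos(phi_b) * math.cos(dl))
    return float(wrap_2pi(math.atan2(y, x)))


def direction_series(track: SpeciesTrack | Sequence[TrackPoint],
                     mode: str = "bearing") -> DirectionSeries:
    """Build the circular direction-change series of a track.

    Zero-length segments (repeated positions) are dropped with a warning;
    the series shortens accordingly.

    Parameters
    ----------
    track
        Time-ordered fixes of one species (>= 2 points for ``bearing``,
        >= 3 for ``turn_angle``; strictly increasing timestamps).
    mode
        ``"bearing"`` (default) or ``"turn_angle"``; see module docstring.
    """
    if mode not in ("bearing", "turn_angle"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(track, SpeciesTrack):
        species, points = track.species, list(track.points)
    else:
        points = list(track)
        species = points[0].species if points else ""

    min_pts = 2 if mode == "bearing" else 3
    if len(points) < min_pts:
        raise TooShortTrackError(
            f"{species or 'track'}: {len(points)} point(s); "
            f"mode={mode} needs at least {min_pts}")
    times = [p.time for p in points]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise TooShortTrackError(
            f"{species or 'track'}: timestamps are not strictly increasing")

    # drop degenerate (repeated-position) segments
    kept = [points[0]]
    dropped = 0
    for p in points[1:]:
        if central_angle(kept[-1], p) < COINCIDENT_TOL:
            dropped += 1
        else:
            kept.append(p)
    if dropped:
        logger.warning("%s: dropped %d zero-length segment(s)",
                       species or "track", dropped)
    if len(kept) < min_pts:
        raise TooShortTrackError(
            f"{species or 'track'}: only {len(kept)} distinct point(s) "
            f"after dropping repeats; mode={mode} needs {min_pts}")

    bearings = np.array([initial_bearing(a, b) for a, b in zip(kept, kept[1:])])
    if mode == "bearing":
        theta = bearings
        anchors = kept[:-1]
    else:
        theta = wrap_2pi(np.diff(bearings))
        anchors = kept[1:-1]
    return DirectionSeries(species=species, theta_rad=theta, mode=mode,
                           anchor_points=anchors, end_point=kept[-1])


def advance(lat_rad: float, lon_rad: float, azimuth: float,
            distance: float) -> tuple[float, float]:
    """Dead-reckon along a great circle.

    From (``lat_rad``, ``lon_rad``), travel an angular ``distance`` at the
    given initial ``azimuth``; returns the destination (lat, lon) in
    radians.  Inverse of :func:`initial_bearing` + :func:`central_angle`
    for a single segment.
    """
    sin_lat2 = (math.sin(lat_rad) * math.cos(distance)
                + math.cos(lat_rad) * math.sin(distance) * math.cos(azimuth))
    lat2 = math.asin(min(1.0, max(-1.0, sin_lat2)))
    lon2 = lon_rad + math.atan2(
        math.sin(azimuth) * math.sin(distance) * math.cos(lat_rad),
        math.cos(distance) - math.sin(lat_rad) * sin_lat2)
    return lat2, float(wrap_pi(lon2))
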