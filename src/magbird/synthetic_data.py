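"""Synthetic tracks and coefficient sets with known ground truth.

No public tracking dataset ships with the package; instead this module
generates everything the pipeline consumes, with the generating mechanism
fully known so recovery can be checked end to end:

* Gauss-coefficient sets — an Earth-like axial dipole (for closed-form
  field identities) or a randomized multipole set with realistically
  decaying degree spectrum;
* uncoupled tracks — headings drawn i.i.d. von Mises(mu, kappa), the
  track advanced by spherical dead-reckoning so that the geodesy module's
  bearing extraction inverts the construction exactly;
* magnetically coupled tracks — the heading mean at each step is shifted
  by the local declination or inclination (its value, or its change since
  the previous fix), by a known coupling strength in [0, 1]; von Mises
  noise on top.  The per-step covariate values and the planted coupling
  are returned as a ground-truth record.

Seeding: one master seed; each stream (headings, coefficients) derives a
child ``numpy.random.Generator`` via ``SeedSequence(master).spawn`` so
stages are independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from . import geomag
from .errors import PolarEscapeError
from .geodesy import SpeciesTrack, TrackPoint, advance, wrap_pi, wrap_2pi
from .geomag import GaussCoefficientSet

#: decay ratio per harmonic degree of the randomized coefficient spectrum
_DEGREE_DECAY = 0.3


@dataclass
class SimulationConfig:
    """Conditions for one simulated track.

    Defaults describe a plausible northward spring migration leg sampled
    a few times a day: ~13 km hops (0.002 rad central angle), northward
    mean heading with moderate concentration (kappa = 4), starting in
    the tropics; a full 500-fix track ends near 60 N, well clear of the
    pole.
    """

    n_points: int = 500
    start_lat: float = 10.0
    start_lon: float = -100.0
    step_angle: float = 0.002
    mu: float = 0.0
    kappa: float = 4.0
    coupling: float = 0.0
    covariate_mode: str = "delta"
    seed: int = 0
    start_time: float = 2020.25
    time_step: float = 1.0 / 365.0
    species: str = "synthetic"

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if not 0.0 < self.step_angle < math.pi / 2:
            raise ValueError("step_angle must lie in (0, pi/2)")
        if self.covariate_mode not in ("point", "delta"):
            raise ValueError("covariate_mode must be 'point' or 'delta'")


def child_rngs(master_seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from one master seed."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(master_seed).spawn(n)]


def synthetic_coefficients(kind: str = "dipole", n_max: int = 12,
                           scale_nT: float = 30_000.0, seed: int = 0,
                           epoch: float = 2020.0,
                           path: str | Path | None = None) -> GaussCoefficientSet:
    """Build a synthetic Gauss-coefficient set.

    ``kind="dipole"`` sets only g[1][0] = -scale_nT (Earth-like sign: the
    axial dipole points the horizontal field toward geographic north, so
    declination vanishes identically and inclination obeys
    tan(I) = 2 tan(latitude)).  ``kind="randomized"`` draws all orders
    with standard deviation ``scale_nT * 0.3^n``, seeded.  Secular
    variation is zero: the synthetic field is static.
    """
    if kind not in ("dipole", "randomized"):
        raise ValueError(f"unknown kind {kind!r}")
    name = f"SYN-{kind.upper()}"
    out = GaussCoefficientSet.zeros(n_max, model_name=name, epoch_t0=epoch)
    if kind == "dipole":
        out.g[1, 0] = -scale_nT
    else:
        rng = np.random.default_rng(seed)
        for n in range(1, n_max + 1):
            sd = scale_nT * _DEGREE_DECAY ** n
            out.g[n, :n + 1] = rng.normal(0.0, sd, size=n + 1)
            out.h[n, 1:n + 1] = rng.normal(0.0, sd, size=n)
    if path is not None:
        geomag.write_cof(out, path)
    return out


def _decimal_year_to_datetime(t: float) -> datetime:
    year = int(math.floor(t))
    start = datetime(year, 1, 1)
    seconds = (datetime(year + 1, 1, 1) - start).total_seconds() * (t - year)
    return start + timedelta(seconds=seconds)


def _simulate(config: SimulationConfig,
              covariate_fn) -> tuple[SpeciesTrack, dict]:
    """Shared dead-reckoning loop.

    ``covariate_fn(lat_deg, lon_deg, t, step_index)`` returns the angular
    covariate (radians) steering the heading mean at the current fix, or
    0.0 for an uncoupled walk.
    """
    rng = np.random.default_rng(config.seed)
    lat = math.radians(config.start_lat)
    lon = math.radians(config.start_lon)
    t = config.start_time
    points = [TrackPoint(config.species, _decimal_year_to_datetime(t),
                         math.degrees(lat), math.degrees(lon))]
    headings, covariates = [], []
    for i in range(config.n_points - 1):
        m_i = float(covariate_fn(math.degrees(lat), math.degrees(lon), t, i))
        mean_i = config.mu + config.coupling * float(wrap_pi(m_i))
        heading = float(wrap_2pi(rng.vonmises(mean_i, config.kappa)))
        lat, lon = advance(lat, lon, heading, config.step_angle)
        if abs(math.degrees(lat)) > 89.9:
            raise PolarEscapeError(
                f"track reached latitude {math.degrees(lat):.2f} at step {i}; "
                "use fewer points or a smaller step_angle")
        t += config.time_step
        points.append(TrackPoint(config.species, _decimal_year_to_datetime(t),
                                 math.degrees(lat), math.degrees(lon)))
        headings.append(heading)
        covariates.append(m_i)
    truth = {
        "species": config.species,
        "seed": config.seed,
        "coupling": config.coupling,
        "mu": config.mu,
        "kappa": config.kappa,
        "covariate_mode": config.covariate_mode,
        "headings": headings,
        "covariate_rad": covariates,
    }
    return SpeciesTrack(config.species, points), truth


def simulate_track_vm(config: SimulationConfig) -> SpeciesTrack:
    """Uncoupled track: headings i.i.d. von Mises(mu, kappa).

    Each fix advances along the great circle at the drawn azimuth by
    ``step_angle``; timestamps advance by ``time_step`` (decimal years).
    """
    track, _ = _simulate(config, lambda *_: 0.0)
    return track


def simulate_coupled_track(config: SimulationConfig,
                           coeffs: GaussCoefficientSet,
                           covariate: str = "inclination"
                           ) -> tuple[SpeciesTrack, dict]:
    """Track whose heading mean is shifted by a geomagnetic angle.

    At each step the chosen covariate (declination or inclination, in
    radians) is evaluated at the current position and time — or, in
    ``covariate_mode="delta"``, its wrapped change since the previous fix
    (zero at the first step).  The heading is drawn from
    von Mises(mu + coupling * M, kappa).  Returns the track plus a
    ground-truth record (planted coupling, per-step covariates, headings)
    sufficient to recompute the covariate series from the same
    coefficient set.
    """
    if covariate not in ("inclination", "declination"):
        raise ValueError("covariate must be 'inclination' or 'declination'")

    prev = {"value": None}

    def field_angle(lat_deg, lon_deg, t, _i):
        ang = geomag.declination_inclination(coeffs, lat_deg, lon_deg, t=t)
        value = math.radians(ang.inclination_deg if covariate == "inclination"
                             else ang.declination_deg)
        if config.covariate_mode == "point":
            return value
        delta = 0.0 if prev["value"] is None else float(wrap_pi(value - prev["value"]))
        prev["value"] = value
        return delta

    track, truth = _simulate(config, field_angle)
    truth["covariate"] = covariate
    truth["model_name"] = coeffs.model_name
    return track, truth


def write_track_csv(track: SpeciesTrack, path: str | Path) -> None:
    """Write a track in the pipeline's default CSV dialect."""
    lines = ["species,timestamp,location-lat,location-long"]
    for p in track.points:
        lines.append(f"{p.species},{p.time.isoformat()},"
                     f"{p.lat_deg!r},{p.lon_deg!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """JSON sidecar with the planted coupling, seed and covariate series."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
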