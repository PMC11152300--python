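"""End-to-end analysis pipeline.

Ingest a tracking CSV, partition by species, extract the circular
direction-change series, evaluate the geomagnetic declination/inclination
covariates along each track, and run per species:

1. Watson U^2 goodness of fit of the direction series (uniformity or
   von Mises with estimated parameters);
2. the circular correlation test of directions against each magnetic
   covariate;
3. circular-circular regression of directions on each covariate, with the
   observed-vs-fitted circular association ("rho").

Covariates can be the field angle at each segment anchor (``mode="point"``)
or its wrapped change across the segment (``mode="delta"``, the default,
since the hypothesis concerns *changes* of the field).  All randomness
(Watson Monte-Carlo / bootstrap critical values) derives from one master
seed, hashed per species so results do not depend on species order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from . import circular_regression, circular_stats, geomag
from .circular_stats import CircCorrResult, WatsonResult
from .errors import (DegenerateDispersionError, EmptyInputError,
                     EmptyResultError, MagbirdError, SchemaError)
from .geodesy import DirectionSeries, SpeciesTrack, TrackPoint, direction_series, wrap_pi
from .geomag import GaussCoefficientSet

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "species": "species",
    "timestamp": "timestamp",
    "lat": "location-lat",
    "lon": "location-long",
}


@dataclass
class AnalysisConfig:
    """Resolved settings for one pipeline run."""

    direction_mode: str = "bearing"
    covariate_mode: str = "delta"
    watson_variant: str = "vonmises_estimated"
    alpha: float = 0.05
    n_boot: int = 500
    min_segments: int = 30
    regression_degree: int = 1
    master_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SpeciesResult:
    """All per-species statistics, or a recorded reason they were skipped."""

    species: str
    n_segments: int
    watson: WatsonResult | None = None
    corr_inclination: CircCorrResult | None = None
    corr_declination: CircCorrResult | None = None
    reg_inclination: dict | None = None
    reg_declination: dict | None = None
    skip_reason: str | None = None

    def to_dict(self) -> dict:
        def corr_dict(c):
            return None if c is None else {
                "r": c.r, "z_stat": c.z_stat, "p_value": c.p_value,
                "n": c.n, "reject": c.reject}

        return {
            "species": self.species,
            "n_segments": self.n_segments,
            "watson": None if self.watson is None else {
                "u2": self.watson.u2, "variant": self.watson.variant,
                "n": self.watson.n,
                "critical_value": self.watson.critical_value,
                "alpha": self.watson.alpha, "reject": self.watson.reject},
            "corr_inclination": corr_dict(self.corr_inclination),
            "corr_declination": corr_dict(self.corr_declination),
            "reg_inclination": self.reg_inclination,
            "reg_declination": self.reg_declination,
            "skip_reason": self.skip_reason,
        }


def decimal_year(when: datetime | str | pd.Timestamp) -> float:
    """Calendar instant as year + elapsed fraction of that year."""
    if isinstance(when, str):
        when = pd.Timestamp(when)
    if isinstance(when, pd.Timestamp):
        when = when.to_pydatetime()
    if not isinstance(when, datetime):
        raise ValueError(f"cannot interpret {when!r} as a date-time")
    start = datetime(when.year, 1, 1, tzinfo=when.tzinfo)
    end = datetime(when.year + 1, 1, 1, tzinfo=when.tzinfo)
    return when.year + ((when - start).total_seconds()
                        / (end - start).total_seconds())


def read_tracks(path: str | Path,
                column_map: dict | None = None) -> list[SpeciesTrack]:
    """Read a tracking CSV into per-species, time-sorted tracks.

    Exact-duplicate rows are dropped (count logged); rows with invalid
    coordinates or unparseable timestamps are rejected individually with
    their line numbers logged.  Species are returned in sorted-name order.
    """
    cols = dict(DEFAULT_COLUMNS, **(column_map or {}))
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; "
                          f"have {list(df.columns)}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    n_dup = int(df.duplicated().sum())
    if n_dup:
        logger.info("%s: dropped %d exact-duplicate row(s)", path, n_dup)
        df = df.drop_duplicates()

    tracks: dict[str, list[TrackPoint]] = {}
    n_bad = 0
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            ts = pd.Timestamp(row[cols["timestamp"]]).to_pydatetime()
            pt = TrackPoint(str(row[cols["species"]]), ts,
                            float(row[cols["lat"]]), float(row[cols["lon"]]))
        except (MagbirdError, ValueError, TypeError) as exc:
            logger.warning("%s:%d: rejected row (%s)", path, lineno, exc)
            n_bad += 1
            continue
        tracks.setdefault(pt.species, []).append(pt)
    if not tracks:
        raise EmptyInputError(f"{path}: no valid rows ({n_bad} rejected)")
    out = []
    for species in sorted(tracks):
        pts = sorted(tracks[species], key=lambda p: p.time)
        out.append(SpeciesTrack(species, pts))
    return out


def magnetic_covariates(series: DirectionSeries, coeffs: GaussCoefficientSet,
                        mode: str = "delta",
                        covariate: str = "inclination") -> np.ndarray:
    """Magnetic covariate series aligned to a direction series, radians.

    ``mode="point"`` evaluates declination or inclination at each
    segment's anchor fix and time; ``mode="delta"`` takes the wrapped
    change of the angle from the segment's start fix to its end fix
    (the next anchor, or the final track point for the last segment).
    """
    if mode not in ("point", "delta"):
        raise ValueError("mode must be 'point' or 'delta'")
    if covariate not in ("inclination", "declination"):
        raise ValueError("covariate must be 'inclination' or 'declination'")
    anchors = series.anchor_points
    if not anchors:
        raise ValueError("direction series has no anchor points")

    def eval_at(p: TrackPoint) -> float:
        try:
            ang = geomag.declination_inclination(
                coeffs, p.lat_deg, p.lon_deg, t=decimal_year(p.time))
        except MagbirdError as exc:
            raise type(exc)(f"at anchor ({p.lat_deg}, {p.lon_deg}): {exc}")
        return math.radians(ang.inclination_deg if covariate == "inclination"
                            else ang.declination_deg)

    values = np.array([eval_at(p) for p in anchors])
    if mode == "point":
        return values
    # each segment's covariate change: evaluate one point past the last anchor
    if series.end_point is None:
        raise ValueError("delta mode needs the series' final track point")
    tail = eval_at(series.end_point)
    return np.asarray(wrap_pi(np.diff(np.append(values, tail))))


def _species_seed(master_seed: int, species: str) -> np.random.SeedSequence:
    digest = hashlib.sha256(species.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(key,))


def run_analysis(tracks: list[SpeciesTrack], coeffs: GaussCoefficientSet,
                 config: AnalysisConfig | None = None) -> list[SpeciesResult]:
    """Run the full per-species analysis; see module docstring.

    Species that fail a prerequisite (too few segments, degenerate
    covariate) are reported with a skip reason instead of aborting the
    run.  Raises only if *no* species is analyzable.
    """
    config = config or AnalysisConfig()
    results: list[SpeciesResult] = []
    any_ok = False
    for track in tracks:
        species = track.species
        try:
            series = direction_series(track, mode=config.direction_mode)
        except MagbirdError as exc:
            results.append(SpeciesResult(species, 0, skip_reason=str(exc)))
            continue
        n_seg = len(series)
        if n_seg < config.min_segments:
            results.append(SpeciesResult(
                species, n_seg,
                skip_reason=f"only {n_seg} segments (< {config.min_segments})"))
            continue
        rng = np.random.default_rng(_species_seed(config.master_seed, species))
        res = SpeciesResult(species, n_seg)
        res.watson = circular_stats.watson_u2(
            series.theta_rad, variant=config.watson_variant,
            alpha=config.alpha, n_boot=config.n_boot, seed=rng)
        for covariate in ("inclination", "declination"):
            try:
                m = magnetic_covariates(series, coeffs,
                                        mode=config.covariate_mode,
                                        covariate=covariate)
                corr = circular_stats.circ_corr_test(
                    series.theta_rad, m, alpha=config.alpha,
                    covariate_label=covariate)
                reg = circular_regression.fit(
                    m, series.theta_rad, m=config.regression_degree,
                    covariate_label=covariate)
                reg_summary = {"degree_m": reg.degree_m,
                               "rho_model": reg.rho_model}
            except (MagbirdError, ValueError) as exc:
                logger.warning("%s/%s: %s", species, covariate, exc)
                corr, reg_summary = None, {"skip_reason": str(exc)}
            setattr(res, f"corr_{covariate}", corr)
            setattr(res, f"reg_{covariate}", reg_summary)
        results.append(res)
        any_ok = True
    if not any_ok:
        reasons = "; ".join(f"{r.species}: {r.skip_reason}" for r in results)
        raise EmptyResultError(f"no species analyzable ({reasons})")
    return results


def write_results(results: list[SpeciesResult], path: str | Path,
                  format: str = "json",
                  config: AnalysisConfig | None = None) -> None:
    """Serialize results, one row/object per species.

    JSON output embeds the resolved configuration (seed included) and is
    byte-stable: rerunning with identical inputs reproduces it exactly.
    """
    if not results:
        raise EmptyResultError("nothing to write")
    path = Path(path)
    if format == "json":
        payload = {
            "config": (config or AnalysisConfig()).to_dict() if config is not None else None,
            "results": [r.to_dict() for r in results],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "csv":
        rows = []
        for r in results:
            d = r.to_dict()
            row = {"species": r.species, "n_segments": r.n_segments,
                   "skip_reason": r.skip_reason or ""}
            w = d["watson"] or {}
            row.update({"watson_u2": w.get("u2"),
                        "watson_critical": w.get("critical_value"),
                        "watson_reject": w.get("reject")})
            for cov in ("inclination", "declination"):
                c = d[f"corr_{cov}"] or {}
                row.update({f"r_{cov}": c.get("r"),
                            f"z_{cov}": c.get("z_stat"),
                            f"p_{cov}": c.get("p_value")})
                g = d[f"reg_{cov}"] or {}
                row[f"rho_{cov}"] = g.get("rho_model")
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
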