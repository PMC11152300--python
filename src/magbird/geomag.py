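"""Main geomagnetic field evaluation from spherical-harmonic coefficients.

The main field is the negative gradient of a scalar potential expanded in
Schmidt semi-normalized spherical harmonics with Gauss coefficients
``g[n][m]``, ``h[n][m]`` (nT) that drift in time about an epoch (linear
secular variation, optionally quadratic).  This module only *evaluates* a
published or synthetic coefficient set; it never fits coefficients to
observatory data, and it ignores crustal/external contributions.

Conventions (standard in geomagnetism):

* geocentric spherical coordinates; latitudes are treated as geocentric on
  the sphere ``r = a`` (no geodetic/geocentric conversion, altitude 0);
* Schmidt semi-normalization ``sqrt(2 (n-m)! / (n+m)!)`` for ``m > 0``,
  no Condon-Shortley phase;
* X north, Y east, Z down, in nT; declination D = atan2(Y, X) and
  inclination I = atan2(Z, sqrt(X^2 + Y^2)), reported in degrees.

Public entry points take latitude/longitude in **degrees** (matching how
field calculators and coefficient files are used); all other angles in the
package are radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (CofFormatError, PoleSingularityError,
                     UndefinedDeclinationError)

#: geomagnetic reference radius (m), close to the mean Earth radius
REFERENCE_RADIUS_M = 6_371_200.0


@dataclass
class GaussCoefficientSet:
    """Gauss coefficients of the main field and their secular variation.

    Arrays are indexed ``[n, m]`` with shape ``(n_max+1, n_max+1)``;
    row 0 and entries with m > n are zero.  ``h[:, 0]`` is zero by
    convention.  Units: nT for g/h, nT/yr for the dots, nT/yr^2 for the
    optional double dots.
    """

    model_name: str
    epoch_t0: float
    n_max: int
    g: np.ndarray
    h: np.ndarray
    gdot: np.ndarray
    hdot: np.ndarray
    gddot: np.ndarray | None = None
    hddot: np.ndarray | None = None
    reference_radius_a: float = REFERENCE_RADIUS_M

    def __post_init__(self):
        shape = (self.n_max + 1, self.n_max + 1)
        for name in ("g", "h", "gdot", "hdot"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        if np.any(self.h[:, 0] != 0.0):
            raise ValueError("h[n][0] must be 0 by convention")

    @classmethod
    def zeros(cls, n_max: int, model_name: str = "ZERO",
              epoch_t0: float = 2020.0) -> "GaussCoefficientSet":
        z = np.zeros((n_max + 1, n_max + 1))
        return cls(model_name, epoch_t0, n_max, z.copy(), z.copy(),
                   z.copy(), z.copy())

    def __add__(self, other: "GaussCoefficientSet") -> "GaussCoefficientSet":
        if self.n_max != other.n_max or self.epoch_t0 != other.epoch_t0:
            raise ValueError("can only add sets with equal n_max and epoch")
        return GaussCoefficientSet(
            f"{self.model_name}+{other.model_name}", self.epoch_t0, self.n_max,
            self.g + other.g, self.h + other.h,
            self.gdot + other.gdot, self.hdot + other.hdot,
            reference_radius_a=self.reference_radius_a)


@dataclass
class LegendreTable:
    """Schmidt semi-normalized associated Legendre values at one argument.

    ``p[n, m]`` holds P̆_n^m(sin(phi)) and ``dp[n, m]`` its derivative with
    respect to latitude phi (not with respect to the argument sin(phi)).
    """

    n_max: int
    p: np.ndarray
    dp: np.ndarray


@dataclass(frozen=True)
class FieldVector:
    """Local field components in nT: X north, Y east, Z down."""

    X: float
    Y: float
    Z: float

    @property
    def horizontal(self) -> float:
        return math.hypot(self.X, self.Y)

    @property
    def total(self) -> float:
        return math.sqrt(self.X ** 2 + self.Y ** 2 + self.Z ** 2)


@dataclass(frozen=True)
class FieldAngles:
    """Declination and inclination in degrees.

    Declination: horizontal-field angle east of geographic north, in
    (-180, 180].  Inclination: dip below the horizontal, in [-90, 90].
    """

    declination_deg: float
    inclination_deg: float


def schmidt_legendre(n_max: int, phi: float) -> LegendreTable:
    """Schmidt semi-normalized associated Legendre functions at sin(phi).

    Stable three-term recursion directly in the normalized functions
    (no Condon-Shortley phase), with derivatives taken with respect to
    the latitude ``phi`` in radians, |phi| <= pi/2.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if not abs(phi) <= math.pi / 2:
        raise ValueError("latitude must lie in [-pi/2, pi/2]")
    x, c = math.sin(phi), math.cos(phi)
    p = np.zeros((n_max + 1, n_max + 1))
    dp = np.zeros((n_max + 1, n_max + 1))
    p[0, 0] = 1.0
    for m in range(1, n_max + 1):
        # diagonal: P̆_mm = sqrt((2m-1)/(2m)) * cos(phi) * P̆_{m-1,m-1},
        # except the Schmidt factor makes the m=1 step plain cos(phi)
        f = 1.0 if m == 1 else math.sqrt((2 * m - 1) / (2.0 * m))
        p[m, m] = f * c * p[m - 1, m - 1]
        dp[m, m] = f * (c * dp[m - 1, m - 1] - x * p[m - 1, m - 1])
    for m in range(0, n_max):
        for n in range(m + 1, n_max + 1):
            a = 2 * n - 1
            b = math.sqrt((n - 1) ** 2 - m * m) if n >= m + 2 else 0.0
            d = math.sqrt(n * n - m * m)
            p[n, m] = (a * x * p[n - 1, m] - b * p[n - 2, m]) / d
            dp[n, m] = (a * (c * p[n - 1, m] + x * dp[n - 1, m])
                        - b * dp[n - 2, m]) / d
    return LegendreTable(n_max=n_max, p=p, dp=dp)


def coefficients_at_time(coeffs: GaussCoefficientSet,
                         t: float) -> GaussCoefficientSet:
    """Propagate coefficients to decimal year ``t``.

    ``g(t) = g + gdot (t - t0) + gddot (t - t0)^2`` (quadratic term only
    when present), likewise for h.  The returned set is instantaneous:
    its secular-variation arrays are zero and its epoch is ``t``.
    """
    if not math.isfinite(t):
        raise ValueError("time must be finite")
    dt = t - coeffs.epoch_t0
    g = coeffs.g + coeffs.gdot * dt
    h = coeffs.h + coeffs.hdot * dt
    if coeffs.gddot is not None:
        g = g + np.asarray(coeffs.gddot) * dt * dt
    if coeffs.hddot is not None:
        h = h + np.asarray(coeffs.hddot) * dt * dt
    z = np.zeros_like(g)
    return GaussCoefficientSet(coeffs.model_name, t, coeffs.n_max, g, h,
                               z, z.copy(),
                               reference_radius_a=coeffs.reference_radius_a)


def _angular_terms(n_max: int, lon_rad: float):
    m = np.arange(n_max + 1)
    return np.cos(m * lon_rad), np.sin(m * lon_rad)


def scalar_potential(coeffs: GaussCoefficientSet, lat_deg: float,
                     lon_deg: float, r: float | None = None,
                     t: float | None = None) -> float:
    """Magnetic scalar potential V (nT*m) at a point.

    ``V = a * sum_n (a/r)^(n+1) sum_m (g cos(m lam) + h sin(m lam))
    * P̆_n^m(sin(phi))`` with m running 0..n.
    """
    a = coeffs.reference_radius_a
    r = a if r is None else float(r)
    if r <= 0:
        raise ValueError("radius must be positive")
    if t is not None:
        coeffs = coefficients_at_time(coeffs, t)
    phi, lam = math.radians(lat_deg), math.radians(lon_deg)
    tab = schmidt_legendre(coeffs.n_max, phi)
    cos_m, sin_m = _angular_terms(coeffs.n_max, lam)
    ratio = a / r
    v = 0.0
    for n in range(1, coeffs.n_max + 1):
        inner = np.sum((coeffs.g[n, :n + 1] * cos_m[:n + 1]
                        + coeffs.h[n, :n + 1] * sin_m[:n + 1])
                       * tab.p[n, :n + 1])
        v += ratio ** (n + 1) * inner
    return a * v


def field_vector(coeffs: GaussCoefficientSet, lat_deg: float, lon_deg: float,
                 r: float | None = None, t: float | None = None) -> FieldVector:
    """Field components (nT) at a point: X north, Y east, Z down.

    Spherical-harmonic synthesis of the negative potential gradient.
    Exact poles are excluded (cos(phi) divides the east component).
    """
    a = coeffs.reference_radius_a
    r = a if r is None else float(r)
    if r <= 0:
        raise ValueError("radius must be positive")
    if abs(lat_deg) >= 90.0:
        raise PoleSingularityError("field components undefined at the poles")
    if t is not None:
        coeffs = coefficients_at_time(coeffs, t)
    phi, lam = math.radians(lat_deg), math.radians(lon_deg)
    tab = schmidt_legendre(coeffs.n_max, phi)
    cos_m, sin_m = _angular_terms(coeffs.n_max, lam)
    m_idx = np.arange(coeffs.n_max + 1)
    ratio = a / r
    x = y = z = 0.0
    for n in range(1, coeffs.n_max + 1):
        gc = coeffs.g[n, :n + 1]
        hc = coeffs.h[n, :n + 1]
        gh_cos = gc * cos_m[:n + 1] + hc * sin_m[:n + 1]
        gh_sin = gc * sin_m[:n + 1] - hc * cos_m[:n + 1]
        rn = ratio ** (n + 2)
        x -= rn * float(np.sum(gh_cos * tab.dp[n, :n + 1]))
        y += rn * float(np.sum(m_idx[:n + 1] * gh_sin * tab.p[n, :n + 1]))
        z -= rn * (n + 1) * float(np.sum(gh_cos * tab.p[n, :n + 1]))
    y /= math.cos(phi)
    return FieldVector(X=x, Y=y, Z=z)


def field_angles(v: FieldVector) -> FieldAngles:
    """Declination and inclination (degrees) of a field vector."""
    h = v.horizontal
    if h < 1e-9:
        raise UndefinedDeclinationError(
            "horizontal intensity below 1e-9 nT; declination undefined")
    d = math.degrees(math.atan2(v.Y, v.X))
    if d <= -180.0:
        d += 360.0
    i = math.degrees(math.atan2(v.Z, h))
    return FieldAngles(declination_deg=d, inclination_deg=i)


def declination_inclination(coeffs: GaussCoefficientSet, lat_deg: float,
                            lon_deg: float, t: float | None = None,
                            r: float | None = None) -> FieldAngles:
    """Convenience: evaluate the field and return its angles (degrees)."""
    return field_angles(field_vector(coeffs, lat_deg, lon_deg, r=r, t=t))


# --- coefficient file I/O -------------------------------------------------
#
# WMM.COF-style plain text: a header line "epoch model_name [release_date]",
# body lines "n m g h gdot hdot", and an optional terminator line of 9s.

def read_cof(path: str | Path) -> GaussCoefficientSet:
    """Read a Gauss-coefficient set from a WMM.COF-style text file."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header = None
    rows: list[tuple[int, int, float, float, float, float]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if set(line.replace(" ", "").replace(".", "")) == {"9"}:
            break  # terminator
        parts = line.split()
        if header is None:
            try:
                epoch = float(parts[0])
            except (ValueError, IndexError):
                raise CofFormatError(f"{path}:{lineno}: bad header {line!r}")
            name = parts[1] if len(parts) > 1 else "UNKNOWN"
            header = (epoch, name)
            continue
        if len(parts) < 6:
            raise CofFormatError(f"{path}:{lineno}: expected 6 fields, got {line!r}")
        try:
            n, m = int(parts[0]), int(parts[1])
            vals = tuple(float(p) for p in parts[2:6])
        except ValueError:
            raise CofFormatError(f"{path}:{lineno}: unparseable row {line!r}")
        if m > n or n < 1 or m < 0:
            raise CofFormatError(f"{path}:{lineno}: invalid degree/order ({n},{m})")
        if any(r[0] == n and r[1] == m for r in rows):
            raise CofFormatError(f"{path}:{lineno}: duplicate entry ({n},{m})")
        rows.append((n, m) + vals)
    if header is None or not rows:
        raise CofFormatError(f"{path}: no header/coefficient rows found")
    n_max = max(r[0] for r in rows)
    out = GaussCoefficientSet.zeros(n_max, model_name=header[1],
                                    epoch_t0=header[0])
    for n, m, gv, hv, gd, hd in rows:
        out.g[n, m], out.h[n, m] = gv, hv
        out.gdot[n, m], out.hdot[n, m] = gd, hd
    if np.any(out.h[:, 0] != 0.0):
        raise CofFormatError(f"{path}: nonzero h for m=0")
    return out


def write_cof(coeffs: GaussCoefficientSet, path: str | Path) -> None:
    """Write a coefficient set in the same text dialect ``read_cof`` reads.

    Uses repr-exact floating formatting so write/read round-trips
    bit-exactly.
    """
    path = Path(path)
    lines = [f"    {coeffs.epoch_t0}            {coeffs.model_name}"]
    for n in range(1, coeffs.n_max + 1):
        for m in range(0, n + 1):
            lines.append(
                f"{n:3d} {m:3d}  {float(coeffs.g[n, m])!r}  {float(coeffs.h[n, m])!r}"
                f"  {float(coeffs.gdot[n, m])!r}  {float(coeffs.hdot[n, m])!r}")
    lines.append("999999999999999999999999999999999999999999999999")
    path.write_text("\n".join(lines) + "\n")
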