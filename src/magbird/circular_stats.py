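"""Circular statistics: von Mises machinery, Watson U^2, circular correlation.

The three inference tools the analysis pipeline runs per species:

* von Mises distribution (density, cdf, sampler, maximum likelihood) — the
  "circular normal", the working model for heading distributions;
* Watson's U^2 goodness-of-fit statistic, against circular uniformity or
  against a von Mises law with estimated parameters, with Monte-Carlo /
  parametric-bootstrap critical values rather than printed tables;
* the circular (sine-moment) correlation coefficient between two angular
  series, with its large-sample standard-normal test.

All angles are radians; samples live on [0, 2*pi).  Functions accepting a
sample take any array-like of angles.

Scaled Bessel functions (``scipy.special.ive``) are used internally so the
density, cdf and MLE stay finite at very large concentrations; the plain
power series for I_p is also exposed (:func:`bessel_i`) since several
oracle checks are stated in terms of it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .errors import (DegenerateDispersionError, TooFewObservationsError,
                     UndefinedMeanError)
from .geodesy import wrap_2pi

TWO_PI = 2.0 * math.pi

#: concentration cap for maximum-likelihood estimates
KAPPA_CAP = 1e4

#: mean resultant length below which the mean direction is undefined
RESULTANT_TOL = 1e-12


@dataclass(frozen=True)
class VonMisesParams:
    """Mean direction mu (wrapped to [0, 2*pi)) and concentration kappa >= 0."""

    mu: float
    kappa: float

    def __post_init__(self):
        if not (math.isfinite(self.kappa) and self.kappa >= 0):
            raise ValueError("kappa must be finite and >= 0")
        object.__setattr__(self, "mu", float(wrap_2pi(self.mu)))


@dataclass(frozen=True)
class WatsonResult:
    """Watson U^2 goodness-of-fit outcome."""

    u2: float
    variant: str
    n: int
    critical_value: float
    alpha: float
    reject: bool


@dataclass(frozen=True)
class CircCorrResult:
    """Circular correlation with its asymptotic normal test."""

    r: float
    z_stat: float
    p_value: float
    n: int
    covariate_label: str = ""

    @property
    def reject(self) -> bool:  # at the level the test was run with
        return bool(self._reject)

    _reject: bool = False


def bessel_i(p: int, k: float) -> float:
    """Modified Bessel function I_p(k) by its power series.

    ``sum_r (k/2)^(2r+p) / (r! (r+p)!)``, summed until the relative
    contribution drops below 1e-14.  Intended for moderate ``k``; the
    distribution functions themselves use scaled Bessel routines.
    """
    if p < 0 or k < 0:
        raise ValueError("order and argument must be non-negative")
    half = k / 2.0
    term = half ** p / math.factorial(p)
    total = term
    r = 0
    while term > 1e-14 * max(total, 1e-300) and r < 10_000:
        r += 1
        term *= half * half / (r * (r + p))
        total += term
    return total


def vm_pdf(theta, params: VonMisesParams):
    """von Mises density ``exp(k cos(t - mu)) / (2 pi I0(k))``.

    ``kappa = 0`` is the circular uniform density ``1/(2 pi)``.
    Evaluated in scaled form so it stays finite for large kappa.
    """
    theta = np.asarray(theta, dtype=float)
    k = params.kappa
    out = np.exp(k * (np.cos(theta - params.mu) - 1.0)) / (TWO_PI * special.i0e(k))
    return float(out) if out.ndim == 0 else out


def vm_cdf(theta, params: VonMisesParams):
    """von Mises cdf on [0, 2*pi], anchored so F(0) = 0 and F(2*pi) = 1.

    Fourier (Bessel) series of the antiderivative:
    ``A(t) = (1/(2 pi)) [ t + (2/I0(k)) sum_p I_p(k) sin(p (t - mu)) / p ]``
    with ``F(t) = A(t) - A(0)``; the series is truncated once the term
    bound ``2 I_p / (p I0)`` falls below 1e-14.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < -1e-12) or np.any(theta > TWO_PI + 1e-12):
        raise ValueError("theta must lie in [0, 2*pi]")
    k = params.kappa
    if k == 0:
        out = theta / TWO_PI
        return float(out) if out.ndim == 0 else out
    i0 = special.i0e(k)
    p_terms = []
    p = 1
    while p < 100_000:
        ratio = special.ive(p, k) / i0
        if 2.0 * ratio / p < 1e-14:
            break
        p_terms.append(ratio)
        p += 1
    orders = np.arange(1, len(p_terms) + 1)
    ratios = np.asarray(p_terms)

    def anti(t):
        t = np.atleast_1d(t)
        s = np.sin(np.multiply.outer(t - params.mu, orders))
        return (t + 2.0 * s @ (ratios / orders)) / TWO_PI

    out = anti(theta) - anti(0.0)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if np.ndim(theta) == 0 else out.reshape(theta.shape)


def vm_sample(n: int, params: VonMisesParams,
              seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` von Mises angles in [0, 2*pi), reproducibly.

    Uses the Best-Fisher rejection sampler (via numpy's generator);
    ``kappa = 0`` degenerates to circular uniform.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return wrap_2pi(rng.vonmises(params.mu, params.kappa, size=n))


def circular_mean(angles) -> float:
    """Mean direction ``atan2(sum sin, sum cos)`` wrapped to [0, 2*pi).

    Undefined (raises) when the resultant vector has zero length, e.g.
    for perfectly antipodal pairs.
    """
    angles = np.asarray(angles, dtype=float)
    s, c = np.sum(np.sin(angles)), np.sum(np.cos(angles))
    if math.hypot(s, c) / max(angles.size, 1) < RESULTANT_TOL:
        raise UndefinedMeanError("zero resultant: mean direction undefined")
    return float(wrap_2pi(math.atan2(s, c)))


def mean_resultant_length(angles) -> float:
    """R-bar, the length of the average unit vector, in [0, 1]."""
    angles = np.asarray(angles, dtype=float)
    return float(np.hypot(np.mean(np.sin(angles)), np.mean(np.cos(angles))))


def _a1(kappa):
    """Bessel ratio A1(kappa) = I1(kappa) / I0(kappa)."""
    return special.i1e(kappa) / special.i0e(kappa)


def _a1_inv(rbar: np.ndarray) -> np.ndarray:
    """Vectorized inverse of A1 by safeguarded Newton, capped at KAPPA_CAP.

    Seeded with the classic rational approximation, then polished to
    ~1e-12 residual; A1'(k) = 1 - A1/k - A1^2.
    """
    rbar = np.atleast_1d(np.asarray(rbar, dtype=float))
    k = np.where(rbar < 0.53, 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6,
                 np.where(rbar < 0.85, -0.4 + 1.39 * rbar + 0.43 / (1 - rbar + 1e-15),
                          1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar + 1e-15)))
    k = np.clip(k, 1e-8, KAPPA_CAP)
    for _ in range(50):
        a = _a1(k)
        deriv = 1.0 - a / k - a * a
        step = np.where(deriv > 1e-300, (a - rbar) / np.maximum(deriv, 1e-300), 0.0)
        k_new = np.clip(k - step, 1e-12, KAPPA_CAP)
        if np.all(np.abs(k_new - k) <= 1e-10 * np.maximum(k, 1.0)):
            k = k_new
            break
        k = k_new
    # at the cap A1 saturates; also map rbar ~ 0 to kappa 0
    k = np.where(rbar < 1e-12, 0.0, k)
    k = np.where(_a1(np.full_like(k, KAPPA_CAP)) <= rbar, KAPPA_CAP, k)
    return k


def vm_mle(angles) -> VonMisesParams:
    """Maximum-likelihood von Mises fit.

    mu-hat is the circular mean; kappa-hat solves ``A1(kappa) = R-bar``
    (bracketed/Newton inversion to 1e-10), capped at ``KAPPA_CAP`` —
    samples with R-bar at or above A1 of the cap (e.g. all angles equal)
    get the cap.  A (near-)zero resultant leaves the mean direction, and
    hence the fit, undefined.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 2:
        raise TooFewObservationsError("need at least 2 angles")
    mu = circular_mean(angles)  # raises UndefinedMeanError on zero resultant
    rbar = mean_resultant_length(angles)
    kappa = float(_a1_inv(rbar)[0])
    return VonMisesParams(mu=mu, kappa=kappa)


def _vm_mle_batch(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise (mu, kappa) MLEs for a matrix of samples. No degeneracy checks."""
    s = np.sin(samples).mean(axis=1)
    c = np.cos(samples).mean(axis=1)
    mu = np.mod(np.arctan2(s, c), TWO_PI)
    kappa = _a1_inv(np.hypot(s, c))
    return mu, kappa


def watson_statistic(u: np.ndarray) -> float:
    """Watson U^2 from probability-integral-transformed values.

    With order statistics U_(1) <= ... <= U_(n),
    ``U^2 = sum_i [ (U_(i) - (2i-1)/(2n)) - (U-bar - 1/2) ]^2 + 1/(12n)``.
    Rotation-invariant analogue of the Cramer-von Mises statistic; equals
    its minimum 1/(12n) when the U's sit exactly at the midpoints.
    """
    u = np.sort(np.asarray(u, dtype=float))
    n = u.size
    mid = (2.0 * np.arange(1, n + 1) - 1.0) / (2.0 * n)
    d = u - mid
    return float(np.sum((d - d.mean()) ** 2) + 1.0 / (12.0 * n))


def _watson_statistic_rows(u: np.ndarray) -> np.ndarray:
    """Row-wise Watson U^2 for a matrix of transformed samples."""
    u = np.sort(u, axis=1)
    n = u.shape[1]
    mid = (2.0 * np.arange(1, n + 1) - 1.0) / (2.0 * n)
    d = u - mid
    return np.sum((d - d.mean(axis=1, keepdims=True)) ** 2, axis=1) + 1.0 / (12.0 * n)


def _vm_cdf_rows(samples: np.ndarray, mu: np.ndarray,
                 kappa: np.ndarray) -> np.ndarray:
    """Row-wise von Mises cdf with per-row parameters (bootstrap helper).

    Same Fourier series as :func:`vm_cdf`, evaluated for all rows at once
    with a common truncation order set by the largest kappa; terms are
    accumulated order by order to keep memory flat.
    """
    mu = np.asarray(mu, dtype=float)[:, None]
    kappa = np.asarray(kappa, dtype=float)
    kmax = float(np.max(kappa)) if kappa.size else 0.0
    i0 = special.i0e(kappa)[:, None]
    p_max = 1
    while p_max < 100_000 and 2.0 * special.ive(p_max, kmax) / (
            p_max * special.i0e(kmax)) >= 1e-14:
        p_max += 1
    f = samples.copy()
    centered = samples - mu
    for p in range(1, p_max):
        ratio = special.ive(p, kappa)[:, None] / i0
        f += (2.0 / p) * ratio * (np.sin(p * centered) + np.sin(p * mu))
    return np.clip(f / TWO_PI, 0.0, 1.0)


def watson_u2(angles, variant: str = "uniformity", alpha: float = 0.05,
              n_boot: int = 500,
              seed: int | np.random.Generator | None = None) -> WatsonResult:
    """Watson U^2 goodness-of-fit test for a circular sample.

    Parameters
    ----------
    angles
        Sample of angles (radians); needs n >= 8.
    variant
        ``"uniformity"`` tests against the circular uniform law;
        ``"vonmises_estimated"`` tests against a von Mises law whose
        parameters are estimated from the sample by maximum likelihood.
    alpha
        Significance level for the critical value.
    n_boot
        Monte-Carlo replicates for the critical value: plain uniform
        simulation for the uniformity variant, a parametric bootstrap
        (re-estimating parameters in each replicate) for the estimated
        variant.
    seed
        Seed or generator for the Monte-Carlo step.

    Returns
    -------
    WatsonResult
        Statistic, critical value at ``alpha``, and the reject decision.
    """
    angles = wrap_2pi(np.asarray(angles, dtype=float))
    n = angles.size
    if n < 8:
        raise TooFewObservationsError(f"Watson test needs n >= 8, got {n}")
    if variant not in ("uniformity", "vonmises_estimated"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if variant == "uniformity":
        u2 = watson_statistic(angles / TWO_PI)
        sims = _watson_statistic_rows(rng.uniform(size=(n_boot, n)))
    else:
        fit = vm_mle(angles)
        u2 = watson_statistic(vm_cdf(angles, fit))
        boot = np.mod(rng.vonmises(fit.mu, fit.kappa, size=(n_boot, n)), TWO_PI)
        mu_b, kappa_b = _vm_mle_batch(boot)
        sims = _watson_statistic_rows(_vm_cdf_rows(boot, mu_b, kappa_b))
    crit = float(np.quantile(sims, 1.0 - alpha))
    return WatsonResult(u2=float(u2), variant=variant, n=n,
                        critical_value=crit, alpha=alpha,
                        reject=bool(u2 > crit))


def _centered_sines(theta, covariate):
    theta = np.asarray(theta, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if theta.shape != covariate.shape or theta.ndim != 1:
        raise ValueError("theta and covariate must be 1-d of equal length")
    st = np.sin(theta - circular_mean(theta))
    sm = np.sin(covariate - circular_mean(covariate))
    return st, sm


def circ_corr(theta, covariate) -> float:
    """Circular correlation coefficient between two angular series.

    ``r = sum sin(t - t_mean) sin(m - m_mean)
    / sqrt(sum sin^2(t - t_mean) * sum sin^2(m - m_mean))``, in [-1, 1];
    invariant to the zero direction of either variable.
    """
    st, sm = _centered_sines(theta, covariate)
    if st.size < 3:
        raise TooFewObservationsError("need n >= 3 for circular correlation")
    ss_t, ss_m = float(np.sum(st ** 2)), float(np.sum(sm ** 2))
    # sums below n * (1e-12)^2 are rounding residue of a constant series
    if ss_t < st.size * 1e-24 or ss_m < sm.size * 1e-24:
        raise DegenerateDispersionError(
            "a series has no dispersion about its mean direction")
    denom = math.sqrt(ss_t * ss_m)
    return float(np.clip(np.sum(st * sm) / denom, -1.0, 1.0))


def circ_corr_test(theta, covariate, alpha: float = 0.05,
                   covariate_label: str = "") -> CircCorrResult:
    """Test H0: circular correlation = 0 against a two-sided alternative.

    Large-sample studentization by the sine moments
    ``lambda_ij = mean( sin^i(t - t_mean) sin^j(m - m_mean) )``:
    ``z = sqrt(n) * r * sqrt(lambda_20 lambda_02 / lambda_22)`` is
    asymptotically standard normal under independence.  Warns below
    n = 25, where the normal approximation is shaky.
    """
    st, sm = _centered_sines(theta, covariate)
    n = st.size
    if n < 4:
        raise TooFewObservationsError("need n >= 4 for the correlation test")
    if n < 25:
        warnings.warn("n < 25: asymptotic null distribution is unreliable",
                      stacklevel=2)
    r = circ_corr(theta, covariate)
    l20 = float(np.mean(st ** 2))
    l02 = float(np.mean(sm ** 2))
    l22 = float(np.mean(st ** 2 * sm ** 2))
    if l22 < 1e-300:
        raise DegenerateDispersionError("degenerate joint sine moments")
    z = math.sqrt(n * l20 * l02 / l22) * r
    p = 2.0 * stats.norm.sf(abs(z))
    return CircCorrResult(r=r, z_stat=float(z), p_value=float(p), n=n,
                          covariate_label=covariate_label,
                          _reject=bool(p < alpha))
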