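"""Circular-circular regression by trigonometric conditional expectations.

To regress a circular response beta on a circular covariate alpha, model
the conditional expectation of the unit vector exp(i beta):

    E[cos beta | alpha] = g1(alpha),   E[sin beta | alpha] = g2(alpha),

and approximate g1, g2 by trigonometric polynomials of degree m:

    g1(alpha) ~ sum_k A_k cos(k alpha) + B_k sin(k alpha)
    g2(alpha) ~ sum_k C_k cos(k alpha) + D_k sin(k alpha)

Both expansions are fitted by ordinary least squares on the shared design
matrix [1, cos a, sin a, ..., cos(m a), sin(m a)]; the error vector
(eps1, eps2) has mean zero and dispersion matrix Sigma.  The predicted
direction is the quadrant-aware angle atan2(g2, g1), which minimizes the
expected squared chord distance E |exp(i beta) - g(alpha)|^2.

The fit quality reported per covariate ("rho") is the circular correlation
between observed and fitted response directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circular_stats import circ_corr
from .errors import (DegenerateCovariateError, UndefinedDirectionError,
                     UnderdeterminedDesignError)
from .geodesy import wrap_2pi


@dataclass
class CircRegFit:
    """Fitted circular-circular regression.

    ``coeff_A[k]``/``coeff_B[k-1]`` are the cosine-model coefficients
    (A_0..A_m, B_1..B_m), ``coeff_C``/``coeff_D`` the sine-model ones.
    """

    degree_m: int
    coeff_A: np.ndarray
    coeff_B: np.ndarray
    coeff_C: np.ndarray
    coeff_D: np.ndarray
    residual_dispersion: np.ndarray
    n: int
    rho_model: float | None = None
    covariate_label: str = ""

    def g1(self, alpha):
        """Fitted E[cos beta | alpha]."""
        return _trig_eval(alpha, self.coeff_A, self.coeff_B)

    def g2(self, alpha):
        """Fitted E[sin beta | alpha]."""
        return _trig_eval(alpha, self.coeff_C, self.coeff_D)


def design_matrix(alpha, m: int) -> np.ndarray:
    """Trigonometric design matrix, columns [1, cos a, sin a, ..., sin(m a)].

    Shape (n, 2m+1); the identically-zero sin(0*a) column is dropped.
    """
    if m < 1:
        raise ValueError("degree m must be >= 1")
    alpha = np.asarray(alpha, dtype=float)
    n = alpha.size
    if n < 2 * m + 1:
        raise UnderdeterminedDesignError(
            f"n={n} rows cannot support degree m={m} (needs {2 * m + 1})")
    cols = [np.ones(n)]
    for k in range(1, m + 1):
        cols.append(np.cos(k * alpha))
        cols.append(np.sin(k * alpha))
    return np.column_stack(cols)


def _trig_eval(alpha, a_coef, b_coef):
    alpha = np.asarray(alpha, dtype=float)
    out = np.full(alpha.shape, float(a_coef[0]))
    for k in range(1, len(a_coef)):
        out = out + a_coef[k] * np.cos(k * alpha) + b_coef[k - 1] * np.sin(k * alpha)
    return out


def fit(alpha, beta, m: int = 1, covariate_label: str = "",
        compute_rho: bool = True) -> CircRegFit:
    """Fit the degree-m circular-circular regression of beta on alpha.

    Two ordinary least-squares problems (for cos beta and sin beta) on the
    shared design matrix; the 2x2 residual cross-moment matrix is stored
    as the error dispersion Sigma.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha.shape != beta.shape or alpha.ndim != 1:
        raise ValueError("alpha and beta must be 1-d of equal length")
    n = alpha.size
    if n < 2 * m + 2:
        raise UnderdeterminedDesignError(
            f"n={n} too small for degree m={m} (needs {2 * m + 2})")
    x = design_matrix(alpha, m)
    y = np.column_stack([np.cos(beta), np.sin(beta)])
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < 2 * m + 1:
        raise DegenerateCovariateError(
            f"design matrix rank {rank} < {2 * m + 1}; covariate degenerate")
    resid = y - x @ coef
    sigma = resid.T @ resid / n
    a_full, c_full = coef[:, 0], coef[:, 1]
    out = CircRegFit(
        degree_m=m,
        coeff_A=a_full[[0] + list(range(1, 2 * m + 1, 2))].copy(),
        coeff_B=a_full[2:2 * m + 1:2].copy(),
        coeff_C=c_full[[0] + list(range(1, 2 * m + 1, 2))].copy(),
        coeff_D=c_full[2:2 * m + 1:2].copy(),
        residual_dispersion=sigma,
        n=n,
        covariate_label=covariate_label,
    )
    if compute_rho:
        out.rho_model = model_rho(out, alpha, beta)
    return out


def predict(fitted: CircRegFit, alpha):
    """Predicted response direction(s) atan2(g2, g1), wrapped to [0, 2*pi)."""
    g1 = np.atleast_1d(fitted.g1(alpha))
    g2 = np.atleast_1d(fitted.g2(alpha))
    if np.any(np.hypot(g1, g2) < 1e-12):
        raise UndefinedDirectionError(
            "both conditional components vanish; direction undefined")
    out = wrap_2pi(np.arctan2(g2, g1))
    return float(out[0]) if np.ndim(alpha) == 0 else out


def model_rho(fitted: CircRegFit, alpha, beta) -> float:
    """Circular association between observed and fitted response.

    The scalar summary reported per covariate: the circular correlation
    of beta with predict(fit, alpha).
    """
    return circ_corr(np.asarray(beta, dtype=float), predict(fitted, alpha))


def select_degree(alpha, beta, m_max: int) -> int:
    """Pick the trigonometric degree by a BIC-like penalized criterion.

    Minimizes mean squared residual of the two linear models plus a
    ``2 (2m+1) ln(n) / n`` complexity penalty; ties go to the smaller m.
    """
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = alpha.size
    if n < 2 * m_max + 2:
        raise UnderdeterminedDesignError(
            f"n={n} too small for m_max={m_max} (needs {2 * m_max + 2})")
    best_m, best_score = None, math.inf
    for m in range(1, m_max + 1):
        f = fit(alpha, beta, m=m, compute_rho=False)
        mse = float(np.trace(f.residual_dispersion))  # (RSS1 + RSS2)/n
        score = mse + 2.0 * (2 * m + 1) * math.log(n) / n
        if score < best_score - 1e-12:
            best_m, best_score = m, score
    return best_m
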