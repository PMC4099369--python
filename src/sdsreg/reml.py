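"""Single-GRM linear mixed model fitted by spectral restricted ML.

Model: ``y = mu 1 + a + e`` with ``a ~ N(0, Theta sigma2_a)`` and
``e ~ N(0, I sigma2_e)``.  Writing ``sigma2_t = sigma2_a + sigma2_e`` and
``h2 = sigma2_a / sigma2_t``, the covariance is ``sigma2_t (h2 Theta +
(1 - h2) I)``.  One eigendecomposition ``Theta = U L U'`` diagonalizes the
problem; in the rotated basis the restricted likelihood is a scalar
function of ``h2`` alone after profiling out ``mu`` (GLS) and ``sigma2_t``
(closed form).  The ratio is maximized over the closed interval [0, 1], so
variance components are non-negative by construction and boundary
solutions are reported as such.

``reml_direct_oracle`` re-derives the same optimum from the dense
covariance matrix (explicit inverses and determinants, grid search plus
local refinement) and exists for cross-validation on small problems.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .relatedness import Grm
from .similarity import PhenotypePanel

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-8
_BOUNDARY_TOL = 1e-6
_H2_XATOL = 1e-8
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class RemlEstimate:
    """REML variance components; ``h2`` is constrained to [0, 1]."""

    sigma2_a: float
    sigma2_e: float
    h2: float
    loglik: float
    at_boundary: bool
    converged: bool
    n_evaluations: int
    identifiable: bool = True


def _check_aligned(panel: PhenotypePanel, grm: Grm) -> None:
    if list(panel.sample_ids) != list(grm.sample_ids):
        raise ValueError("phenotype and GRM sample IDs differ; align first")
    if panel.n < 3:
        raise ValueError("need n >= 3 individuals")


def _profiled_terms(
    h2: float, lam: np.ndarray, y_rot: np.ndarray, x_rot: np.ndarray
) -> tuple[float, float, float]:
    """(sigma2_t_hat, mu_hat, restricted loglik) at a given ratio h2."""
    n = y_rot.size
    w = h2 * lam + (1.0 - h2)
    inv_w = 1.0 / w
    xwx = float((x_rot * x_rot) @ inv_w)
    mu = float((x_rot * y_rot) @ inv_w) / xwx
    r = y_rot - mu * x_rot
    quad = float((r * r) @ inv_w)
    sigma2_t = quad / (n - 1)
    loglik = -0.5 * (
        (n - 1) * _LOG2PI
        + (n - 1) * np.log(sigma2_t)
        + float(np.log(w).sum())
        + np.log(xwx)
        + (n - 1)
    )
    return sigma2_t, mu, float(loglik)


def restricted_loglik(
    panel: PhenotypePanel, grm: Grm, h2: float, sigma2_t: float
) -> float:
    """Restricted log-likelihood at explicit ``(h2, sigma2_t)``, eigenbasis route.

    Profiles only the intercept; used to anchor the spectral computation
    against dense-matrix evaluations in tests.
    """
    _check_aligned(panel, grm)
    lam, u = eigh(grm.theta)
    y_rot = u.T @ panel.y
    x_rot = u.T @ np.ones(panel.n)
    n = panel.n
    w = h2 * lam + (1.0 - h2)
    inv_w = 1.0 / w
    xwx = float((x_rot * x_rot) @ inv_w)
    mu = float((x_rot * y_rot) @ inv_w) / xwx
    r = y_rot - mu * x_rot
    quad = float((r * r) @ inv_w) / sigma2_t
    return float(
        -0.5
        * (
            (n - 1) * _LOG2PI
            + (n - 1) * np.log(sigma2_t)
            + float(np.log(w).sum())
            + np.log(xwx)
            + quad
        )
    )


def spectral_reml(panel: PhenotypePanel, grm: Grm) -> RemlEstimate:
    """Fit the intercept-only single-GRM mixed model by profile REML.

    Eigenvalues below 1e-8 are clipped with a warning (rounding can leave
    tiny negatives even for a valid GRM).  When the GRM spectrum is flat
    (e.g. the identity) the split into genetic and residual variance is
    unidentifiable: the fit is reported at the zero boundary with
    ``identifiable=False`` rather than at an arbitrary interior point.
    """
    _check_aligned(panel, grm)
    n = panel.n
    lam, u = eigh(grm.theta)
    if lam.min() < _EIG_FLOOR:
        # rank-deficient marker GRMs (m < n) always carry round-off
        # negatives of order 1e-14; only a materially negative spectrum
        # deserves a visible warning
        level = logging.WARNING if lam.min() < -1e-6 else logging.DEBUG
        logger.log(
            level,
            "GRM is near-singular (min eigenvalue %.3g); clipping to %.0e",
            lam.min(),
            _EIG_FLOOR,
        )
        lam = np.clip(lam, _EIG_FLOOR, None)
    y_rot = u.T @ panel.y
    x_rot = u.T @ np.ones(n)

    if lam.max() - lam.min() < 1e-10:
        # flat spectrum: likelihood depends on sigma2_a + sigma2_e only
        scale = float(lam.mean())
        sigma2_t, _, loglik = _profiled_terms(0.0, lam / scale, y_rot, x_rot)
        return RemlEstimate(
            sigma2_a=0.0,
            sigma2_e=sigma2_t,
            h2=0.0,
            loglik=loglik,
            at_boundary=True,
            converged=True,
            n_evaluations=1,
            identifiable=False,
        )

    def negll(h2: float) -> float:
        return -_profiled_terms(h2, lam, y_rot, x_rot)[2]

    res = minimize_scalar(
        negll, bounds=(0.0, 1.0), method="bounded", options={"xatol": _H2_XATOL}
    )
    candidates = [(float(res.x), -float(res.fun))]
    for h2_edge in (0.0, 1.0):
        candidates.append((h2_edge, -negll(h2_edge)))
    h2_hat, loglik = max(candidates, key=lambda c: c[1])
    if not np.isfinite(loglik):
        raise ValueError("non-finite restricted likelihood")
    at_boundary = h2_hat <= _BOUNDARY_TOL or h2_hat >= 1.0 - _BOUNDARY_TOL
    if h2_hat <= _BOUNDARY_TOL:
        h2_hat = 0.0
    elif h2_hat >= 1.0 - _BOUNDARY_TOL:
        h2_hat = 1.0
    sigma2_t, _, loglik = _profiled_terms(h2_hat, lam, y_rot, x_rot)
    return RemlEstimate(
        sigma2_a=h2_hat * sigma2_t,
        sigma2_e=(1.0 - h2_hat) * sigma2_t,
        h2=h2_hat,
        loglik=loglik,
        at_boundary=at_boundary,
        converged=bool(res.success),
        n_evaluations=int(res.nfev) + 3,
    )


def reml_direct_oracle(
    panel: PhenotypePanel, grm: Grm, grid: int = 1001
) -> RemlEstimate:
    """Dense-matrix REML by grid search plus local refinement (tests only).

    Builds ``V0 = h2 Theta + (1 - h2) I`` explicitly at each candidate
    ratio, profiles the intercept and total variance through dense solves,
    and scores the restricted likelihood with ``slogdet``.  Limited to
    n <= 200.
    """
    _check_aligned(panel, grm)
    n = panel.n
    if n > 200:
        raise ValueError("direct oracle is restricted to n <= 200")
    theta = grm.theta
    y = panel.y
    ones = np.ones(n)
    eye = np.eye(n)

    def negll(h2: float) -> float:
        v0 = h2 * theta + (1.0 - h2) * eye
        sign, logdet = np.linalg.slogdet(v0)
        if sign <= 0:
            return np.inf
        v0_inv = np.linalg.inv(v0)
        xwx = float(ones @ v0_inv @ ones)
        mu = float(ones @ v0_inv @ y) / xwx
        r = y - mu
        quad = float(r @ v0_inv @ r)
        if quad <= 0:
            return np.inf
        sigma2_t = quad / (n - 1)
        return 0.5 * (
            (n - 1) * _LOG2PI
            + (n - 1) * np.log(sigma2_t)
            + logdet
            + np.log(xwx)
            + (n - 1)
        )

    h2_grid = np.linspace(0.0, 1.0, grid)
    scores = np.array([negll(h) for h in h2_grid])
    if np.ptp(scores[np.isfinite(scores)]) < 1e-10:
        mu = y.mean()
        quad = float((y - mu) @ (y - mu))
        sigma2_t = quad / (n - 1)
        return RemlEstimate(
            sigma2_a=0.0,
            sigma2_e=sigma2_t,
            h2=0.0,
            loglik=-float(negll(0.0)),
            at_boundary=True,
            converged=True,
            n_evaluations=grid,
            identifiable=False,
        )
    k = int(np.nanargmin(scores))
    lo = h2_grid[max(k - 1, 0)]
    hi = h2_grid[min(k + 1, grid - 1)]
    res = minimize_scalar(
        negll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    candidates = [(float(res.x), float(res.fun)), (0.0, float(scores[0])), (1.0, float(scores[-1]))]
    h2_hat, neg = min(candidates, key=lambda c: c[1])
    at_boundary = h2_hat <= _BOUNDARY_TOL or h2_hat >= 1.0 - _BOUNDARY_TOL
    v0 = h2_hat * theta + (1.0 - h2_hat) * eye
    v0_inv = np.linalg.inv(v0)
    xwx = float(ones @ v0_inv @ ones)
    mu = float(ones @ v0_inv @ y) / xwx
    r = y - mu
    sigma2_t = float(r @ v0_inv @ r) / (n - 1)
    return RemlEstimate(
        sigma2_a=h2_hat * sigma2_t,
        sigma2_e=(1.0 - h2_hat) * sigma2_t,
        h2=h2_hat,
        loglik=-neg,
        at_boundary=at_boundary,
        converged=bool(res.success),
        n_evaluations=grid + int(res.nfev),
    )
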