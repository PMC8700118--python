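"""Marginal-maximum-likelihood EM estimation of the unidimensional 2PL.

The marginal likelihood

    l(a, b) = sum_p w_p log int prod_i psi(a_i(theta-b_i))^{x_pi}
                                      [1-psi(a_i(theta-b_i))]^{1-x_pi} f(theta) dtheta

is maximized over a discrete quadrature grid (default 21 points on
[-5, 5] with renormalized standard-normal weights).  Scored entries may
be fractional (pseudo-likelihood: a cell x in (0,1) contributes x to the
expected success count and 1-x to the failure count), missing entries
contribute nothing, and persons may carry nonnegative weights.

Identification fixes the ability distribution to N(0, 1).  The latent
background (latent-regression) variant replaces the common prior by a
person-specific normal N(gamma0 + gamma1 Z_p, sigma_e^2) and standardizes
the theta metric after estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

from .scoring import ScoredMatrix

__all__ = [
    "QuadratureGrid",
    "ScaledFit",
    "default_grid",
    "fit_2pl",
    "fit_2pl_latent_regression",
    "person_posterior",
]

logger = logging.getLogger(__name__)

A_BOUNDS = (0.05, 8.0)
B_BOUNDS = (-8.0, 8.0)


@dataclass
class QuadratureGrid:
    """Ordered quadrature points with normalized prior weights."""

    points: np.ndarray
    prior_weights: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.prior_weights = np.asarray(self.prior_weights, dtype=float)
        if np.any(np.diff(self.points) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if np.any(self.prior_weights < 0):
            raise ValueError("prior weights must be nonnegative")
        self.prior_weights = self.prior_weights / self.prior_weights.sum()

    @property
    def size(self) -> int:
        return len(self.points)


def default_grid(n_points: int = 21, lo: float = -5.0, hi: float = 5.0) -> QuadratureGrid:
    """Equally spaced grid with renormalized standard-normal weights."""
    pts = np.linspace(lo, hi, n_points)
    w = np.exp(-0.5 * pts**2)
    return QuadratureGrid(points=pts, prior_weights=w / w.sum())


@dataclass
class ScaledFit:
    """Result of a 2PL fit: item parameters, log-likelihood and posteriors."""

    discrimination: np.ndarray
    difficulty: np.ndarray
    loglik: float
    n_params: int
    posterior: np.ndarray  # persons x grid, rows sum to 1
    grid: QuadratureGrid
    converged: bool
    n_iter: int
    loglik_history: np.ndarray
    provenance: str = "2PL"
    gamma0: float | None = None
    gamma1: float | None = None
    sigma_e: float | None = None
    boundary_items: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def item_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"a": self.discrimination, "b": self.difficulty}
        )


def _prepare(scored, weights):
    values = scored.values if isinstance(scored, ScoredMatrix) else np.asarray(scored, float)
    n, _ = values.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("person weights must be nonnegative")
    r = (~np.isnan(values)).astype(float)
    x = np.nan_to_num(values)
    u1 = x * r          # fractional success weight per cell
    u0 = (1.0 - x) * r  # fractional failure weight
    return values, u1, u0, w


def _item_loglik_tables(a, b, points):
    eta = a[:, None] * (points[None, :] - b[:, None])
    return log_expit(eta), log_expit(-eta)  # log P, log (1-P), items x grid


def _mstep_newton(a, b, n1, n0, points, n_steps=5):
    """Per-item Newton updates of (a, b) on expected counts, all items at once.

    Uses the expected (Fisher) information of the complete-data objective
    with step halving so the objective never decreases; estimates are
    clipped to the admissible box.
    """
    def q_value(a_, b_):
        lp, lq = _item_loglik_tables(a_, b_, points)
        return (n1 * lp + n0 * lq).sum(axis=1)

    q_old = q_value(a, b)
    for _ in range(n_steps):
        eta = a[:, None] * (points[None, :] - b[:, None])
        p = expit(eta)
        tot = n1 + n0
        e = n1 - tot * p            # score residuals, items x grid
        d = points[None, :] - b[:, None]
        g_a = (e * d).sum(axis=1)
        g_b = -a * e.sum(axis=1)
        w = tot * p * (1.0 - p)
        i_aa = (w * d * d).sum(axis=1)
        i_ab = -a * (w * d).sum(axis=1)
        i_bb = a**2 * w.sum(axis=1)
        det = i_aa * i_bb - i_ab**2
        det = np.where(det > 1e-12, det, 1e-12)
        da = (i_bb * g_a - i_ab * g_b) / det
        db = (-i_ab * g_a + i_aa * g_b) / det
        step = np.ones_like(a)
        for _ in range(10):
            a_new = np.clip(a + step * da, *A_BOUNDS)
            b_new = np.clip(b + step * db, *B_BOUNDS)
            q_new = q_value(a_new, b_new)
            bad = q_new < q_old - 1e-12
            if not np.any(bad):
                break
            step[bad] *= 0.5
        improved = q_new >= q_old - 1e-12
        a = np.where(improved, a_new, a)
        b = np.where(improved, b_new, b)
        q_old = np.where(improved, q_new, q_old)
        if np.max(np.abs(g_a)) + np.max(np.abs(g_b)) < 1e-8:
            break
    return a, b


def _start_values(u1, u0, w):
    tot = (w[:, None] * (u1 + u0)).sum(axis=0)
    succ = (w[:, None] * u1).sum(axis=0)
    prop = np.clip(succ / np.maximum(tot, 1e-12), 0.01, 0.99)
    b0 = -np.log(prop / (1.0 - prop))
    return np.ones_like(b0), np.clip(b0, -4.0, 4.0)


def fit_2pl(
    scored,
    weights=None,
    grid: QuadratureGrid | None = None,
    max_iter: int = 1000,
    tol_ll: float = 1e-9,
    tol_par: float = 1e-5,
) -> ScaledFit:
    """EM maximum of the 2PL marginal (pseudo-)likelihood.

    Missing entries are ignored (only observed responses contribute);
    fractional entries weight the success/failure expected counts.  Items
    with all-equal observed values are flagged and kept at the parameter
    bounds rather than raising.
    """
    values, u1, u0, w = _prepare(scored, weights)
    grid = grid or default_grid()
    pts = grid.points
    log_prior = np.log(grid.prior_weights)

    a, b = _start_values(u1, u0, w)
    tot = (w[:, None] * (u1 + u0)).sum(axis=0)
    succ = (w[:, None] * u1).sum(axis=0)
    boundary = np.where((succ < 1e-9) | (tot - succ < 1e-9))[0]
    if boundary.size:
        logger.warning("items %s have all-equal observed values; estimates bounded",
                       boundary.tolist())

    ll_old = -np.inf
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp, lq = _item_loglik_tables(a, b, pts)
        logl = u1 @ lp + u0 @ lq + log_prior[None, :]
        m = logl.max(axis=1, keepdims=True)
        lik = np.exp(logl - m)
        norm = lik.sum(axis=1)
        ll = float(np.dot(w, np.log(norm) + m[:, 0]))
        history.append(ll)
        h = lik / norm[:, None]

        wh = w[:, None] * h
        n1 = u1.T @ wh
        n0 = u0.T @ wh
        a_new, b_new = _mstep_newton(a, b, n1, n0, pts)

        par_change = max(np.max(np.abs(a_new - a)), np.max(np.abs(b_new - b)))
        rel = abs(ll - ll_old) / (abs(ll) + 1.0)
        a, b = a_new, b_new
        ll_old = ll
        if rel < tol_ll or par_change < tol_par:
            converged = True
            break
    if not converged:
        logger.warning("2PL EM did not converge in %d iterations", max_iter)

    lp, lq = _item_loglik_tables(a, b, pts)
    logl = u1 @ lp + u0 @ lq + log_prior[None, :]
    m = logl.max(axis=1, keepdims=True)
    lik = np.exp(logl - m)
    norm = lik.sum(axis=1)
    ll = float(np.dot(w, np.log(norm) + m[:, 0]))
    h = lik / norm[:, None]

    return ScaledFit(
        discrimination=a,
        difficulty=b,
        loglik=ll,
        n_params=2 * len(a),
        posterior=h,
        grid=grid,
        converged=converged,
        n_iter=it,
        loglik_history=np.asarray(history),
        boundary_items=boundary,
    )


def fit_2pl_latent_regression(
    scored,
    covariate,
    weights=None,
    grid: QuadratureGrid | None = None,
    max_iter: int = 1000,
    tol_ll: float = 1e-9,
    tol_par: float = 1e-5,
) -> ScaledFit:
    """2PL with a latent background model theta_p | Z_p ~ N(g0 + g1 Z_p, s_e^2).

    The regression is estimated freely; afterwards the theta metric is
    standardized (marginal mean 0, SD 1) and the item parameters and
    regression coefficients rescaled accordingly, so all treatments share
    one identification convention.  A constant covariate degenerates to
    the plain 2PL fit.
    """
    z = np.asarray(covariate, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("covariate must be finite")
    if np.ptp(z) < 1e-12:
        logger.info("constant covariate; falling back to the standard 2PL fit")
        fit = fit_2pl(scored, weights, grid, max_iter, tol_ll, tol_par)
        fit.provenance = "2PL+LBM(constant)"
        return fit

    values, u1, u0, w = _prepare(scored, weights)
    grid = grid or default_grid()
    pts = grid.points

    a, b = _start_values(u1, u0, w)
    g0, g1, s_e = 0.0, 0.0, 1.0
    wsum = w.sum()

    ll_old = -np.inf
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu_p = g0 + g1 * z
        log_prior = -0.5 * ((pts[None, :] - mu_p[:, None]) / s_e) ** 2
        log_prior -= np.log(np.exp(log_prior).sum(axis=1, keepdims=True))

        lp, lq = _item_loglik_tables(a, b, pts)
        logl = u1 @ lp + u0 @ lq + log_prior
        m = logl.max(axis=1, keepdims=True)
        lik = np.exp(logl - m)
        norm = lik.sum(axis=1)
        ll = float(np.dot(w, np.log(norm) + m[:, 0]))
        history.append(ll)
        h = lik / norm[:, None]

        wh = w[:, None] * h
        n1 = u1.T @ wh
        n0 = u0.T @ wh
        a_new, b_new = _mstep_newton(a, b, n1, n0, pts)

        # weighted regression of the posterior ability distribution on Z
        theta_bar = h @ pts
        zbar = np.dot(w, z) / wsum
        tbar = np.dot(w, theta_bar) / wsum
        szz = np.dot(w, (z - zbar) ** 2) / wsum
        szt = np.dot(w, (z - zbar) * (theta_bar - tbar)) / wsum
        g1_new = szt / max(szz, 1e-12)
        g0_new = tbar - g1_new * zbar
        resid2 = (wh * (pts[None, :] - (g0_new + g1_new * z)[:, None]) ** 2).sum()
        s_e_new = float(np.sqrt(max(resid2 / wsum, 1e-6)))

        par_change = max(
            np.max(np.abs(a_new - a)),
            np.max(np.abs(b_new - b)),
            abs(g0_new - g0),
            abs(g1_new - g1),
            abs(s_e_new - s_e),
        )
        rel = abs(ll - ll_old) / (abs(ll) + 1.0)
        a, b, g0, g1, s_e = a_new, b_new, g0_new, g1_new, s_e_new
        ll_old = ll
        if rel < tol_ll or par_change < tol_par:
            converged = True
            break
    if not converged:
        logger.warning("latent-regression EM did not converge in %d iterations", max_iter)

    # standardize the theta metric: marginal mean 0, SD 1
    mu_p = g0 + g1 * z
    mu = np.dot(w, mu_p) / wsum
    var = np.dot(w, (mu_p - mu) ** 2) / wsum + s_e**2
    s = float(np.sqrt(var))
    a_std = a * s
    b_std = (b - mu) / s
    g0_std, g1_std, s_e_std = (g0 - mu) / s, g1 / s, s_e / s

    log_prior = -0.5 * ((pts[None, :] - mu_p[:, None]) / s_e) ** 2
    log_prior -= np.log(np.exp(log_prior).sum(axis=1, keepdims=True))
    lp, lq = _item_loglik_tables(a, b, pts)
    logl = u1 @ lp + u0 @ lq + log_prior
    m = logl.max(axis=1, keepdims=True)
    lik = np.exp(logl - m)
    norm = lik.sum(axis=1)
    ll = float(np.dot(w, np.log(norm) + m[:, 0]))
    h = lik / norm[:, None]

    return ScaledFit(
        discrimination=a_std,
        difficulty=b_std,
        loglik=ll,
        n_params=2 * len(a) + 3,
        posterior=h,
        grid=grid,
        converged=converged,
        n_iter=it,
        loglik_history=np.asarray(history),
        provenance="2PL+LBM",
        gamma0=g0_std,
        gamma1=g1_std,
        sigma_e=s_e_std,
    )


def person_posterior(fit: ScaledFit, responses) -> np.ndarray:
    """Normalized posterior over the grid for one scored response row.

    An all-missing row returns the prior weights exactly.
    """
    row = np.asarray(responses, dtype=float).ravel()
    r = ~np.isnan(row)
    if not np.any(r):
        return fit.grid.prior_weights.copy()
    lp, lq = _item_loglik_tables(fit.discrimination, fit.difficulty, fit.grid.points)
    x = np.nan_to_num(row)
    logl = (x * r) @ lp + ((1.0 - x) * r) @ lq + np.log(fit.grid.prior_weights)
    lik = np.exp(logl - logl.max())
    return lik / lik.sum()
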