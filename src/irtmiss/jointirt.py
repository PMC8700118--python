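"""Joint models for item responses and response indicators.

The Mislevy-Wu family models the pair (X_pi, R_pi) given a bivariate
normal (theta_p, xi_p) with Var(theta) = 1, SD(xi) and Cor(theta, xi)
estimated.  Response probabilities follow the 2PL; the indicator model is

    P(R_pi = 1 | X_pi, theta_p, xi_p) = psi(xi_p - beta_i - delta_i X_pi).

Within the administered mask the pair is a three-category variable V_pi
(0 = observed incorrect, 1 = observed correct, 2 = missing) with

    P(V=0) = (1 - P_i(theta)) psi(xi - beta_i)
    P(V=1) = P_i(theta) psi(xi - beta_i - delta_i)
    P(V=2) = P_i(theta) (1 - psi(xi - beta_i - delta_i))
             + (1 - P_i(theta)) (1 - psi(xi - beta_i))

Configurations: delta_i = 0 with Cor fixed to 0 is the ignorable model
(MO1); delta_i = 0 with free Cor is the latent-ignorable model (MO2);
delta_i clamped to -10 reproduces scoring-as-wrong (MW); a common free
delta is MM1 and format-specific deltas are MM2.  Estimation is EM over
a product quadrature (21 x 21 nodes on [-5, 5]), the prior being
reweighted from the current (SD(xi), Cor) each M-step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .datagen import ResponseData

__all__ = [
    "JointSpec",
    "JointFit",
    "ThreeCategoryMatrix",
    "Grid2D",
    "default_grid2d",
    "to_three_category",
    "category_probabilities",
    "fit_joint",
    "n_parameters",
    "JOINT_SPECS",
    "Recipe",
    "model_registry",
    "MODEL_LABELS",
]

logger = logging.getLogger(__name__)

A_BOUNDS = (0.05, 8.0)
B_BOUNDS = (-8.0, 8.0)
BETA_BOUNDS = (-10.0, 10.0)
DELTA_BOUNDS = (-10.0, 3.0)
SD_XI_BOUNDS = (0.05, 10.0)
COR_BOUNDS = (-0.99, 0.99)
WRONG_DELTA = -10.0


class ConfigurationError(ValueError):
    """Raised for unknown model labels or inconsistent specifications."""


@dataclass(frozen=True)
class JointSpec:
    """Configuration of the joint model's missingness part."""

    delta_mode: str  # "zero" | "fixed" | "common" | "by_format"
    fixed_value: float = 0.0
    correlation_free: bool = True
    sd_xi_free: bool = True

    def __post_init__(self) -> None:
        if self.delta_mode not in ("zero", "fixed", "common", "by_format"):
            raise ConfigurationError(f"unknown delta mode {self.delta_mode!r}")


JOINT_SPECS: dict[str, JointSpec] = {
    "MO1": JointSpec("zero", correlation_free=False),
    "MO2": JointSpec("zero"),
    "MW": JointSpec("fixed", fixed_value=WRONG_DELTA),
    "MM1": JointSpec("common"),
    "MM2": JointSpec("by_format"),
}


@dataclass
class ThreeCategoryMatrix:
    """V in {0, 1, 2}; -1 marks not-administered cells."""

    values: np.ndarray


def to_three_category(data: ResponseData) -> ThreeCategoryMatrix:
    """Bijective recoding of (X, R) within the administered mask."""
    v = np.full(data.observed.shape, -1, dtype=np.int8)
    adm = data.administered == 1
    obs = (data.indicators == 1) & adm
    v[obs] = data.observed[obs].astype(np.int8)
    v[(data.indicators == 0) & adm] = 2
    return ThreeCategoryMatrix(values=v)


@dataclass
class Grid2D:
    """Product quadrature over (theta, xi)."""

    theta_points: np.ndarray
    xi_points: np.ndarray

    def __post_init__(self) -> None:
        self.theta_points = np.asarray(self.theta_points, dtype=float)
        self.xi_points = np.asarray(self.xi_points, dtype=float)
        t, x = np.meshgrid(self.theta_points, self.xi_points, indexing="ij")
        self.nodes_theta = t.ravel()
        self.nodes_xi = x.ravel()

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.theta_points), len(self.xi_points)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes_theta)

    def log_prior(self, sd_xi: float, cor: float) -> np.ndarray:
        """Normalized log prior weights from the bivariate normal density."""
        t, x = self.nodes_theta, self.nodes_xi
        det = sd_xi**2 * (1.0 - cor**2)
        q = (
            t**2 * sd_xi**2 - 2.0 * cor * sd_xi * t * x + x**2
        ) / det
        lp = -0.5 * q
        lp -= np.log(np.exp(lp - lp.max()).sum()) + lp.max()
        return lp


def default_grid2d(n_points: int = 21, lo: float = -5.0, hi: float = 5.0) -> Grid2D:
    pts = np.linspace(lo, hi, n_points)
    return Grid2D(theta_points=pts, xi_points=pts)


def category_probabilities(a, b, beta, delta, theta, xi):
    """(p0, p1, p2) of the three-category variable at scalar item parameters.

    ``theta`` and ``xi`` broadcast; used directly by tests and imputation.
    """
    p = expit(a * (np.asarray(theta) - b))
    q0 = expit(np.asarray(xi) - beta)
    q1 = expit(np.asarray(xi) - beta - delta)
    p0 = (1.0 - p) * q0
    p1 = p * q1
    p2 = p * (1.0 - q1) + (1.0 - p) * (1.0 - q0)
    return p0, p1, p2


@dataclass
class JointFit:
    """Fitted joint model for (X, R)."""

    discrimination: np.ndarray
    difficulty: np.ndarray
    beta: np.ndarray
    delta: np.ndarray  # per item
    delta_mode: str
    sd_xi: float
    cor: float
    loglik: float
    n_params: int
    posterior: np.ndarray  # persons x nodes
    grid: Grid2D
    converged: bool
    n_iter: int
    loglik_history: np.ndarray
    provenance: str = "joint"
    delta_by_format: dict = field(default_factory=dict)

    def item_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "a": self.discrimination,
                "b": self.difficulty,
                "beta": self.beta,
                "delta": self.delta,
            }
        )


def n_parameters(spec: JointSpec, n_items: int, n_formats: int = 2) -> int:
    """Free-parameter count: 2I (a, b) + I (beta) + free deltas + globals."""
    k = 3 * n_items
    if spec.delta_mode == "common":
        k += 1
    elif spec.delta_mode == "by_format":
        k += n_formats
    if spec.sd_xi_free:
        k += 1
    if spec.correlation_free:
        k += 1
    return k


def _delta_design(spec: JointSpec, n_items: int, formats) -> tuple[np.ndarray, list]:
    """Map free delta parameters to items.

    Returns (membership matrix D with delta_i = D @ d_free, group labels);
    empty for zero/fixed modes.
    """
    if spec.delta_mode in ("zero", "fixed"):
        return np.zeros((n_items, 0)), []
    if spec.delta_mode == "common":
        return np.ones((n_items, 1)), ["common"]
    fmts = np.asarray(formats, dtype=object)
    groups = list(dict.fromkeys(fmts.tolist()))
    if len(groups) == 1:
        logger.info("single item format present; format-specific delta degenerates "
                    "to a common delta")
    d = np.stack([(fmts == g).astype(float) for g in groups], axis=1)
    return d, groups


def _expected_q_and_grad(x, c0, c1, c2, grid, d_design, fixed_delta, n_items):
    """Expected complete-data log-likelihood and gradient, all items at once.

    Parameter vector ``x`` = [a, b, beta, d_free]; ``c0``/``c1``/``c2`` are
    posterior-expected counts per item and node with theta varying along
    rows of the (T, U) reshape.
    """
    nt, nu = grid.shape
    tp, xp = grid.theta_points, grid.xi_points
    i = n_items
    a, b, beta = x[:i], x[i:2 * i], x[2 * i:3 * i]
    d_free = x[3 * i:]
    delta = d_design @ d_free if d_design.shape[1] else np.full(i, fixed_delta)

    eta = a[:, None] * (tp[None, :] - b[:, None])          # I x T
    p = expit(eta)
    e0 = xp[None, :] - beta[:, None]                        # I x U
    e1 = e0 - delta[:, None]
    q0 = expit(e0)
    q1 = expit(e1)

    c0t, c0u = c0.sum(axis=2), c0.sum(axis=1)               # I x T, I x U
    c1t, c1u = c1.sum(axis=2), c1.sum(axis=1)

    with np.errstate(divide="ignore"):
        lp, l1mp = log_expit(eta), log_expit(-eta)
        lq0, l1mq0 = log_expit(e0), log_expit(-e0)
        lq1, l1mq1 = log_expit(e1), log_expit(-e1)

    p2 = p[:, :, None] * (1.0 - q1[:, None, :]) + (1.0 - p[:, :, None]) * (
        1.0 - q0[:, None, :]
    )
    p2 = np.clip(p2, 1e-300, None)

    q = (
        (c1t * lp).sum() + (c0t * l1mp).sum()
        + (c1u * lq1).sum() + (c0u * lq0).sum()
        + (c2 * np.log(p2)).sum()
    )

    # gradients
    r2 = c2 / p2                                            # I x T x U
    g2_t = np.einsum("itu,iu->it", r2, q0 - q1)             # d p2 / d P_t factor
    score_t = c1t * (1.0 - p) - c0t * p + p * (1.0 - p) * g2_t
    g_a = (score_t * (tp[None, :] - b[:, None])).sum(axis=1)
    g_b = -a * score_t.sum(axis=1)

    s0 = q0 * (1.0 - q0)                                    # I x U
    s1 = q1 * (1.0 - q1)
    r2_pt = np.einsum("itu,it->iu", r2, p)                  # sum_t r2 * P_t
    r2_1mpt = np.einsum("itu,it->iu", r2, 1.0 - p)
    g_beta = (
        -(c1u * (1.0 - q1)).sum(axis=1)
        - (c0u * (1.0 - q0)).sum(axis=1)
        + (r2_pt * s1).sum(axis=1)
        + (r2_1mpt * s0).sum(axis=1)
    )
    grad = np.concatenate([g_a, g_b, g_beta])
    if d_design.shape[1]:
        g_delta_i = -(c1u * (1.0 - q1)).sum(axis=1) + (r2_pt * s1).sum(axis=1)
        grad = np.concatenate([grad, d_design.T @ g_delta_i])
    return -q, -grad


def _start_values(v, formats, spec):
    n_items = v.shape[1]
    obs = v >= 0
    answered = (v == 0) | (v == 1)
    n_ans = np.maximum(answered.sum(axis=0), 1)
    prop = np.clip((v == 1).sum(axis=0) / n_ans, 0.01, 0.99)
    b0 = np.clip(-np.log(prop / (1.0 - prop)), -4.0, 4.0)
    n_adm = np.maximum(obs.sum(axis=0), 1)
    miss = np.clip((v == 2).sum(axis=0) / n_adm, 1e-3, 0.99)
    beta0 = np.clip(np.log(miss / (1.0 - miss)), *BETA_BOUNDS)
    return np.ones(n_items), b0, beta0


def fit_joint(
    data: ResponseData,
    formats=None,
    spec: JointSpec | str = "MM1",
    grid: Grid2D | None = None,
    weights=None,
    max_iter: int = 500,
    tol_ll: float = 1e-8,
    tol_par: float = 1e-4,
    mstep_iter: int = 8,
    delta_starts: tuple = (0.0, -4.0, -9.0),
    pilot_iter: int = 40,
) -> JointFit:
    """EM maximum of the three-category likelihood over the 2-D quadrature.

    ``spec`` is a :class:`JointSpec` or one of the registry labels
    MO1 / MO2 / MW / MM1 / MM2.  theta is standard normal; the mean of xi
    is 0 with SD(xi) and Cor(theta, xi) estimated when free.  The M-step
    updates all item parameters in one bounded quasi-Newton call with
    analytic gradients (a generalized M-step: the expected complete-data
    log-likelihood increases but need not be fully maximized).

    When delta is free its likelihood can be multimodal (a strongly
    negative delta trades off against the response-propensity part), so
    the EM is piloted for ``pilot_iter`` iterations from each value in
    ``delta_starts`` and continued from the best pilot.
    """
    label = spec if isinstance(spec, str) else None
    if isinstance(spec, str):
        if spec not in JOINT_SPECS:
            raise ConfigurationError(f"unknown joint model label {spec!r}")
        spec = JOINT_SPECS[spec]
    grid = grid or default_grid2d()
    v = to_three_category(data).values
    n, n_items = v.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    if spec.delta_mode == "by_format" and formats is None:
        raise ConfigurationError("format-specific deltas require item formats")

    m0 = (v == 0).astype(float)
    m1 = (v == 1).astype(float)
    m2 = (v == 2).astype(float)
    no_missing = np.where(m2.sum(axis=0) == 0)[0]
    if no_missing.size:
        logger.warning("items %s have no missing responses; beta at bound",
                       no_missing.tolist())

    d_design, d_groups = _delta_design(spec, n_items, formats)
    fixed_delta = spec.fixed_value if spec.delta_mode == "fixed" else 0.0

    a, b, beta = _start_values(v, formats, spec)
    d_free = np.zeros(d_design.shape[1])
    sd_xi, cor = 1.0, 0.0

    nt, nu = grid.shape
    tp, xp = grid.theta_points, grid.xi_points
    node_t2 = grid.nodes_theta**2
    node_x2 = grid.nodes_xi**2
    node_tx = grid.nodes_theta * grid.nodes_xi

    bounds = (
        [A_BOUNDS] * n_items + [B_BOUNDS] * n_items + [BETA_BOUNDS] * n_items
        + [DELTA_BOUNDS] * d_design.shape[1]
    )

    def estep(a, b, beta, delta, sd_xi, cor):
        eta = a[:, None] * (tp[None, :] - b[:, None])
        e0 = xp[None, :] - beta[:, None]
        e1 = e0 - delta[:, None]
        lp, l1mp = log_expit(eta), log_expit(-eta)
        lq0, lq1 = log_expit(e0), log_expit(e1)
        p = expit(eta)
        q0, q1 = expit(e0), expit(e1)
        p2 = p[:, :, None] * (1.0 - q1[:, None, :]) + (1.0 - p[:, :, None]) * (
            1.0 - q0[:, None, :]
        )
        logp2 = np.log(np.clip(p2, 1e-300, None)).reshape(n_items, -1)

        l_theta = m1 @ lp + m0 @ l1mp                      # N x T
        l_xi = m1 @ lq1 + m0 @ lq0                         # N x U
        logl = (l_theta[:, :, None] + l_xi[:, None, :]).reshape(n, -1)
        logl += m2 @ logp2
        logl += grid.log_prior(sd_xi, cor)[None, :]
        mx = logl.max(axis=1, keepdims=True)
        lik = np.exp(logl - mx)
        norm = lik.sum(axis=1)
        ll = float(np.dot(w, np.log(norm) + mx[:, 0]))
        return ll, lik / norm[:, None]

    def run_em(state, n_iter):
        a, b, beta, d_free, sd_xi, cor = state
        ll_old = -np.inf
        history = []
        converged = False
        it = 0
        for it in range(1, n_iter + 1):
            delta = (d_design @ d_free if d_design.shape[1]
                     else np.full(n_items, fixed_delta))
            ll, h = estep(a, b, beta, delta, sd_xi, cor)
            history.append(ll)

            wh = w[:, None] * h
            c0 = (m0.T @ wh).reshape(n_items, nt, nu)
            c1 = (m1.T @ wh).reshape(n_items, nt, nu)
            c2 = (m2.T @ wh).reshape(n_items, nt, nu)

            x0 = np.concatenate([a, b, beta, d_free])
            res = minimize(
                _expected_q_and_grad,
                x0,
                args=(c0, c1, c2, grid, d_design, fixed_delta, n_items),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": mstep_iter},
            )
            x = res.x
            a_new, b_new = x[:n_items], x[n_items:2 * n_items]
            beta_new = x[2 * n_items:3 * n_items]
            d_new = x[3 * n_items:]

            # prior update: constrained normal MLE with Var(theta) = 1, means 0
            hw = wh.sum(axis=0) / wsum
            s11 = float(hw @ node_t2)
            s12 = float(hw @ node_tx)
            s22 = float(hw @ node_x2)
            sd_new, cor_new = sd_xi, cor
            if spec.correlation_free:
                c_reg = s12 / max(s11, 1e-12)
                tau2 = max(s22 - s12**2 / max(s11, 1e-12), 1e-6)
                sd_new = float(np.clip(np.sqrt(c_reg**2 + tau2), *SD_XI_BOUNDS))
                cor_new = float(np.clip(c_reg / sd_new, *COR_BOUNDS))
            elif spec.sd_xi_free:
                sd_new = float(np.clip(np.sqrt(max(s22, 1e-6)), *SD_XI_BOUNDS))

            par_change = max(
                np.max(np.abs(a_new - a)),
                np.max(np.abs(b_new - b)),
                np.max(np.abs(beta_new - beta)),
                np.max(np.abs(d_new - d_free)) if d_free.size else 0.0,
                abs(sd_new - sd_xi),
                abs(cor_new - cor),
            )
            rel = abs(ll - ll_old) / (abs(ll) + 1.0)
            a, b, beta, d_free = a_new, b_new, beta_new, d_new
            sd_xi, cor = sd_new, cor_new
            ll_old = ll
            if rel < tol_ll or par_change < tol_par:
                converged = True
                break
        return (a, b, beta, d_free, sd_xi, cor), ll_old, history, converged, it

    a0, b0, beta0 = a, b, beta
    if d_design.shape[1]:
        pilots = []
        for d0 in delta_starts:
            state0 = (a0, b0, beta0, np.full(d_design.shape[1], d0), 1.0, 0.0)
            pilots.append(run_em(state0, pilot_iter))
        best = max(pilots, key=lambda p: p[1])
        state, _, history, converged, it = best
        if not converged:
            state, _, hist2, converged, it2 = run_em(state, max_iter - pilot_iter)
            history = history + hist2
            it += it2
    else:
        state0 = (a0, b0, beta0, np.zeros(0), 1.0, 0.0)
        state, _, history, converged, it = run_em(state0, max_iter)
    a, b, beta, d_free, sd_xi, cor = state
    if not converged:
        logger.warning("joint EM did not converge in %d iterations", max_iter)

    delta = d_design @ d_free if d_design.shape[1] else np.full(n_items, fixed_delta)
    ll, h = estep(a, b, beta, delta, sd_xi, cor)

    return JointFit(
        discrimination=a,
        difficulty=b,
        beta=beta,
        delta=delta,
        delta_mode=spec.delta_mode,
        sd_xi=sd_xi,
        cor=cor,
        loglik=ll,
        n_params=n_parameters(spec, n_items, max(len(d_groups), 1)),
        posterior=h,
        grid=grid,
        converged=converged,
        n_iter=it,
        loglik_history=np.asarray(history),
        provenance=label or f"joint-{spec.delta_mode}",
        delta_by_format=dict(zip(d_groups, d_free)),
    )


# ---------------------------------------------------------------------------
# Registry of the 19 treatment pipelines

@dataclass(frozen=True)
class Recipe:
    """Scoring / model / imputation recipe behind one treatment label."""

    label: str
    strategy: str                 # "U" (unmodeled), "M" (model-based), "I" (imputation)
    scoring: str | None = None    # "wrong" | "omitted_wrong" | "partial" | "ignore"
    covariate: str | None = None  # latent background model predictor
    joint: str | None = None      # joint-model label fitted or imputed from
    imputation: str | None = None  # "model" | "partial" | "fcs1" | "fcs2"


_REGISTRY: dict[str, Recipe] = {
    "UW": Recipe("UW", "U", scoring="wrong"),
    "MW": Recipe("MW", "M", joint="MW"),
    "IW": Recipe("IW", "I", joint="MW", imputation="model"),
    "UP": Recipe("UP", "U", scoring="partial"),
    "IP": Recipe("IP", "I", imputation="partial"),
    "UN1": Recipe("UN1", "U", scoring="omitted_wrong"),
    "UN2": Recipe("UN2", "U", scoring="omitted_wrong", covariate="not_reached"),
    "UO1": Recipe("UO1", "U", scoring="ignore"),
    "MO1": Recipe("MO1", "M", joint="MO1"),
    "IO1": Recipe("IO1", "I", joint="MO1", imputation="model"),
    "UO2": Recipe("UO2", "U", scoring="ignore", covariate="all_missing"),
    "MO2": Recipe("MO2", "M", joint="MO2"),
    "IO2": Recipe("IO2", "I", joint="MO2", imputation="model"),
    "MM1": Recipe("MM1", "M", joint="MM1"),
    "IM1": Recipe("IM1", "I", joint="MM1", imputation="model"),
    "MM2": Recipe("MM2", "M", joint="MM2"),
    "IM2": Recipe("IM2", "I", joint="MM2", imputation="model"),
    "IF1": Recipe("IF1", "I", imputation="fcs1"),
    "IF2": Recipe("IF2", "I", imputation="fcs2"),
}

MODEL_LABELS = tuple(_REGISTRY)


def model_registry(label: str) -> Recipe:
    """Pipeline configuration for one of the 19 treatment labels."""
    try:
        return _REGISTRY[label]
    except KeyError:
        raise ConfigurationError(
            f"unknown model label {label!r}; known: {', '.join(_REGISTRY)}"
        ) from None
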