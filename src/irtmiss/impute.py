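"""Multiple imputation of missing item responses.

Three families:

* model-based imputation from a fitted joint model — draw (theta*, xi*)
  per person from the 2-D posterior, then impute each missing cell from
  the Bayes-rule probability

      P(X=1 | R=0, theta*, xi*) =
          P(R=0|X=1, xi*) P(X=1|theta*) / sum_x P(R=0|X=x, xi*) P(X=x|theta*),

* partially-correct guessing imputation (missing MC cells Bernoulli(1/K),
  CR cells 0; no model required),

* fully conditional specification (FCS): cycle over incomplete columns,
  regress each on the other items (optionally plus the other response
  indicators), compress predictors to a few PLS factors, and impute by
  predictive mean matching (PMM) so imputed values are always values
  observed in the data.

Five imputed datasets are created by default; they are stacked into one
long dataset and rescaled with the 2PL rather than combined by pooling
rules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .datagen import ItemBank, ResponseData
from .irt2pl import QuadratureGrid, ScaledFit, fit_2pl
from .jointirt import JointFit

__all__ = [
    "ImputationSet",
    "LatentDrawsPosterior",
    "imputation_probability",
    "draw_posterior_latents",
    "impute_model_based",
    "impute_partial_guess",
    "fcs_impute",
    "stack_and_scale",
]

logger = logging.getLogger(__name__)


@dataclass
class ImputationSet:
    """m completed response matrices; observed cells identical to the input."""

    datasets: list[np.ndarray]
    source: str
    seed: int | None = None

    @property
    def m(self) -> int:
        return len(self.datasets)

    def stacked(self) -> np.ndarray:
        return np.vstack(self.datasets)

    def to_long_frame(self, item_ids=None):
        """One long table with an ``.imp`` index column (1..m)."""
        import pandas as pd

        cols = (np.arange(self.datasets[0].shape[1])
                if item_ids is None else np.asarray(item_ids))
        frames = []
        for j, d in enumerate(self.datasets, start=1):
            df = pd.DataFrame(d, columns=cols)
            df.insert(0, ".imp", j)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False, na_rep="NA")


@dataclass
class LatentDrawsPosterior:
    """Per-person posterior draws (theta*, xi*) on the quadrature nodes."""

    theta: np.ndarray
    xi: np.ndarray
    node_index: np.ndarray


def imputation_probability(fit: JointFit, theta_star, xi_star, item: int):
    """Posterior probability of a correct response given missingness.

    With delta = 0 this reduces to the 2PL probability psi(a(theta*-b));
    with delta = -10 it is numerically zero (a missing response implies an
    incorrect one).
    """
    a = fit.discrimination[item]
    b = fit.difficulty[item]
    beta = fit.beta[item]
    delta = fit.delta[item]
    p1 = expit(a * (np.asarray(theta_star, dtype=float) - b))
    xi = np.asarray(xi_star, dtype=float)
    miss_if_1 = 1.0 - expit(xi - beta - delta)
    miss_if_0 = 1.0 - expit(xi - beta)
    num = miss_if_1 * p1
    den = num + miss_if_0 * (1.0 - p1)
    return num / np.clip(den, 1e-300, None)


def draw_posterior_latents(
    fit: JointFit,
    data: ResponseData | None = None,
    rng: np.random.Generator | int | None = None,
) -> LatentDrawsPosterior:
    """One categorical draw per person from the 2-D posterior over grid nodes."""
    rng = np.random.default_rng(rng)
    h = fit.posterior
    cum = np.cumsum(h, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(h.shape[0])
    idx = np.array([np.searchsorted(cum[p], u[p], side="right") for p in range(len(u))])
    idx = np.minimum(idx, h.shape[1] - 1)
    return LatentDrawsPosterior(
        theta=fit.grid.nodes_theta[idx],
        xi=fit.grid.nodes_xi[idx],
        node_index=idx,
    )


def impute_model_based(
    fit: JointFit,
    data: ResponseData,
    m: int = 5,
    rng: np.random.Generator | int | None = None,
) -> ImputationSet:
    """Bernoulli imputation at the Bayes-rule probabilities, m times.

    Each copy uses fresh posterior latent draws.  Sourced from MW this
    yields treatment IW, from MO1 -> IO1, MO2 -> IO2, MM1 -> IM1,
    MM2 -> IM2.
    """
    rng = np.random.default_rng(rng)
    miss = (data.indicators == 0) & (data.administered == 1)
    persons, items = np.nonzero(miss)
    out = []
    for _ in range(m):
        lat = draw_posterior_latents(fit, data, rng)
        filled = data.observed.copy()
        if persons.size:
            a = fit.discrimination[items]
            b = fit.difficulty[items]
            beta = fit.beta[items]
            delta = fit.delta[items]
            p1 = expit(a * (lat.theta[persons] - b))
            miss_if_1 = 1.0 - expit(lat.xi[persons] - beta - delta)
            miss_if_0 = 1.0 - expit(lat.xi[persons] - beta)
            num = miss_if_1 * p1
            prob = num / np.clip(num + miss_if_0 * (1.0 - p1), 1e-300, None)
            filled[persons, items] = (rng.random(persons.size) < prob).astype(float)
        out.append(filled)
    return ImputationSet(out, source=f"model:{fit.provenance}")


def impute_partial_guess(
    data: ResponseData,
    bank: ItemBank,
    m: int = 5,
    rng: np.random.Generator | int | None = None,
) -> ImputationSet:
    """Random-guessing imputation: missing MC ~ Bernoulli(1/K_i), missing CR -> 0."""
    is_mc = bank.format == "MC"
    if np.any(is_mc & ~np.isfinite(bank.n_options)):
        raise ValueError("every MC item needs n_options for guessing imputation")
    rng = np.random.default_rng(rng)
    p_guess = np.where(is_mc, 1.0 / bank.n_options, 0.0)
    miss = (data.indicators == 0) & (data.administered == 1)
    persons, items = np.nonzero(miss)
    out = []
    for _ in range(m):
        filled = data.observed.copy()
        filled[persons, items] = (
            rng.random(persons.size) < p_guess[items]
        ).astype(float)
        out.append(filled)
    return ImputationSet(out, source="partial")


def _pls_pmm_column(y_obs, x_obs, x_all, n_factors, n_donors, rng):
    """Predict a column from PLS factors and impute by donor matching."""
    from sklearn.cross_decomposition import PLSRegression

    keep = x_obs.std(axis=0) > 1e-10
    if not np.any(keep) or np.ptp(y_obs) < 1e-12:
        # no usable predictors or constant target: every donor predicts alike
        pred_all = np.full(x_all.shape[0], y_obs.mean())
        pred_obs = np.full(x_obs.shape[0], y_obs.mean())
    else:
        x_obs = x_obs[:, keep]
        x_all = x_all[:, keep]
        k = int(min(n_factors, x_obs.shape[1], x_obs.shape[0] - 1))
        pls = PLSRegression(n_components=max(k, 1), scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(x_obs, y_obs)
        pred_obs = pls.predict(x_obs).ravel()
        pred_all = pls.predict(x_all).ravel()
    return pred_obs, pred_all


def fcs_impute(
    data: ResponseData,
    include_indicators: bool = False,
    n_pls_factors: int = 10,
    m: int = 5,
    n_cycles: int = 10,
    pmm_donors: int = 5,
    rng: np.random.Generator | int | None = None,
    booklet=None,
) -> ImputationSet:
    """FCS imputation with PLS dimension reduction and predictive mean matching.

    For the target column the predictors are all other item columns
    (treatment IF1) or the other item columns plus all response-indicator
    columns except the target's own (IF2).  Each chain starts from
    marginal draws and runs ``n_cycles`` cycles before the dataset is
    stored; PMM copies the value of one of ``pmm_donors`` observed donors
    nearest in predicted value, so imputations only take observed values.
    With ``booklet`` given, the algorithm runs separately per booklet
    group.
    """
    rng = np.random.default_rng(rng)
    if booklet is not None:
        groups = np.asarray(booklet)
        out = [data.observed.copy() for _ in range(m)]
        for g in np.unique(groups):
            sel = groups == g
            sub = ResponseData(
                observed=data.observed[sel],
                indicators=data.indicators[sel],
                administered=data.administered[sel],
            )
            sub_imp = fcs_impute(
                sub, include_indicators, n_pls_factors, m, n_cycles, pmm_donors, rng
            )
            for j in range(m):
                out[j][sel] = sub_imp.datasets[j]
        return ImputationSet(out, source="fcs2" if include_indicators else "fcs1")

    obs_mask = data.indicators == 1
    adm = data.administered == 1
    miss_mask = (~obs_mask) & adm
    n, n_items = data.observed.shape
    incomplete = np.where(miss_mask.any(axis=0))[0]
    for v in incomplete:
        if not obs_mask[:, v].any():
            raise ValueError(f"column {v} has no observed values; cannot impute")
    r_cols = obs_mask.astype(float)

    out = []
    for _ in range(m):
        filled = data.observed.copy()
        for v in incomplete:  # start chains from marginal draws
            p = np.nanmean(data.observed[:, v])
            idx = np.where(miss_mask[:, v])[0]
            filled[idx, v] = (rng.random(idx.size) < p).astype(float)
        for _ in range(n_cycles):
            for v in incomplete:
                rows_obs = obs_mask[:, v]
                rows_mis = miss_mask[:, v]
                cols = np.arange(n_items) != v
                x = filled[:, cols]
                if include_indicators:
                    x = np.hstack([x, r_cols[:, cols]])
                y_obs = filled[rows_obs, v]
                pred_obs, pred_all = _pls_pmm_column(
                    y_obs, x[rows_obs], x, n_pls_factors, pmm_donors, rng
                )
                pred_mis = pred_all[rows_mis]
                # PMM: uniform pick among the nearest observed donors
                dist = np.abs(pred_mis[:, None] - pred_obs[None, :])
                k = min(pmm_donors, pred_obs.size)
                donor_pool = np.argpartition(dist, k - 1, axis=1)[:, :k]
                pick = donor_pool[
                    np.arange(donor_pool.shape[0]),
                    rng.integers(0, k, size=donor_pool.shape[0]),
                ]
                filled[rows_mis, v] = y_obs[pick]
        out.append(filled)
    return ImputationSet(out, source="fcs2" if include_indicators else "fcs1")


def stack_and_scale(
    imps: ImputationSet,
    weights=None,
    grid: QuadratureGrid | None = None,
    **fit_kwargs,
) -> ScaledFit:
    """Stack the m completed datasets and fit the 2PL to the long data.

    Each stacked row keeps its person weight; by likelihood scale
    invariance the item estimates do not depend on the common weight
    factor m.
    """
    stacked = imps.stacked()
    if weights is None:
        w = None
    else:
        w = np.tile(np.asarray(weights, dtype=float), imps.m)
    fit = fit_2pl(stacked, weights=w, grid=grid, **fit_kwargs)
    fit.provenance = f"2PL(stacked:{imps.source})"
    return fit
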