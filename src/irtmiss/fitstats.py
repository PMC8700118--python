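"""Model-fit statistics and survey variance machinery.

AIC/BIC for model comparison, the Gilula-Haberman penalty (GHP) as a
sample-size-free effect size of fit, balanced-repeated-replication (BRR)
standard errors from replicate weights, and posterior-weighted means on
a transformed metric (the numerical equivalent of averaging many
plausible values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeightSet",
    "FitComparison",
    "information_criteria",
    "ghp",
    "compare_fits",
    "brr_se",
    "weighted_posterior_mean",
]

GHP_NOTABLE = 0.001


@dataclass
class WeightSet:
    """Base person weights plus R replicate weight columns and scaling factor A."""

    base: np.ndarray
    replicates: np.ndarray  # persons x R
    scale: float = 0.05

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        self.replicates = np.asarray(self.replicates, dtype=float)
        if self.replicates.ndim != 2 or self.replicates.shape[1] < 1:
            raise ValueError("need at least one replicate weight column")
        if np.any(self.base < 0) or np.any(self.replicates < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[1]


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = -2 loglik + 2k and BIC = -2 loglik + k log n (n = persons)."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(n)
    return float(aic), float(bic)


def ghp(aic: float, administered_items_per_person, params_per_item: int = 2) -> float:
    """Gilula-Haberman penalty: AIC / (2 sum_p I_p).

    I_p counts the estimated parameters attributed to person p:
    ``params_per_item`` times the number of administered items (2 for the
    2PL; configurable for joint models that also estimate beta per item).
    """
    items = np.asarray(administered_items_per_person, dtype=float)
    denom = 2.0 * params_per_item * items.sum()
    if denom <= 0:
        raise ValueError("zero administered items; GHP undefined")
    return float(aic / denom)


def compare_fits(
    fits: dict,
    n_persons: int,
    administered_items_per_person,
    params_per_item: dict | int = 2,
) -> pd.DataFrame:
    """BIC/GHP comparison table across fitted models.

    ``fits`` maps labels to objects with ``loglik`` and ``n_params``.
    The best model minimizes BIC; GHP gaps above 0.001 are flagged as
    notable.
    """
    rows = []
    for label, fit in fits.items():
        ppi = params_per_item[label] if isinstance(params_per_item, dict) else params_per_item
        aic, bic = information_criteria(fit.loglik, fit.n_params, n_persons)
        rows.append(
            {
                "model": label,
                "loglik": fit.loglik,
                "k": fit.n_params,
                "AIC": aic,
                "BIC": bic,
                "GHP": ghp(aic, administered_items_per_person, ppi),
            }
        )
    df = pd.DataFrame(rows)
    df["best_bic"] = df["BIC"] == df["BIC"].min()
    df["ghp_gap"] = df["GHP"] - df["GHP"].min()
    df["notable"] = df["ghp_gap"] > GHP_NOTABLE
    return df


def brr_se(full_estimate: float, replicate_estimates, scale: float = 0.05) -> float:
    """BRR standard error sqrt(A sum_r (est_r - est)^2), A = 0.05 in PISA.

    Applies unchanged to single means and to between-model mean
    differences computed per replicate.
    """
    reps = np.asarray(replicate_estimates, dtype=float)
    if reps.size < 1:
        raise ValueError("need at least one replicate estimate")
    return float(np.sqrt(scale * np.sum((reps - full_estimate) ** 2)))


def weighted_posterior_mean(posteriors, weights, transform=(0.0, 1.0)) -> float:
    """Weight-normalized average of posterior-expected transformed ability.

    ``posteriors`` is persons x grid (rows normalized) over grid points
    theta_t; ``transform`` = (nu0, nu1) maps to the reporting metric.
    The grid points are taken from the second argument when ``posteriors``
    is a (matrix, points) pair.
    """
    if isinstance(posteriors, tuple):
        h, points = posteriors
    else:
        raise TypeError("pass (posterior_matrix, grid_points)")
    h = np.asarray(h, dtype=float)
    points = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    nu0, nu1 = transform
    person_means = h @ (nu0 + nu1 * points)
    return float(np.dot(w, person_means) / w.sum())
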