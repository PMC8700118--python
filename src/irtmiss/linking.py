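"""Haberman linking of group-specific 2PL item parameters.

Separate scalings fix each group's ability distribution to N(0, 1); a
linear map theta -> nu0_c + nu1_c * theta per group places everybody on a
common metric.  Haberman linking finds the maps by two least-squares
stages over the common items:

    stage 1 (discriminations):  log a_ic = log a_i + log nu1_c
    stage 2 (difficulties):     nu1_c b_ic + nu0_c = b_i

with the reference group's (nu0, nu1) fixed to (0, 1).  Because each
group was standardized, (nu0_c, nu1_c) are the group's mean and SD on
the common metric.  For two groups the solution coincides with
log-mean-mean linking.  In a simulation, linking estimates to the true
item parameters (truth as reference) returns the estimated population
mean and SD on the true metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LinkResult",
    "haberman_link",
    "link_to_truth",
    "to_reporting_metric",
]

logger = logging.getLogger(__name__)


class LinkingError(ValueError):
    """Raised when the groups do not support a link."""


@dataclass
class LinkResult:
    """Per-group transformation and linked common item parameters."""

    groups: list
    nu0: dict
    nu1: dict
    common_a: pd.Series
    common_b: pd.Series

    def means(self) -> pd.Series:
        return pd.Series(self.nu0, name="mean")

    def sds(self) -> pd.Series:
        return pd.Series(self.nu1, name="sd")


def _as_table(params) -> pd.DataFrame:
    if isinstance(params, pd.DataFrame):
        df = params.copy()
        if "item" not in df.columns:
            df = df.reset_index(names="item")
        return df[["item", "a", "b"]]
    a, b = params
    return pd.DataFrame({"item": np.arange(len(a)), "a": np.asarray(a, float),
                         "b": np.asarray(b, float)})


def haberman_link(params_by_group: dict, reference=None) -> LinkResult:
    """Two-stage least-squares link of per-group item parameter tables.

    ``params_by_group`` maps a group label to a table with columns
    (item, a, b) or an (a, b) array pair.  Items are matched by the item
    column; groups must share at least two common items overall.
    Nonpositive discriminations are excluded with a warning.
    """
    if len(params_by_group) < 2:
        raise LinkingError("need at least two groups to link")
    groups = list(params_by_group)
    reference = groups[0] if reference is None else reference
    tables = {g: _as_table(t) for g, t in params_by_group.items()}

    rows = []
    for g, df in tables.items():
        bad = df["a"] <= 0
        if bad.any():
            logger.warning("group %s: %d nonpositive discriminations excluded",
                           g, int(bad.sum()))
            df = df[~bad]
        for _, r in df.iterrows():
            rows.append((g, r["item"], float(r["a"]), float(r["b"])))
    long = pd.DataFrame(rows, columns=["group", "item", "a", "b"])
    counts = long.groupby("item")["group"].nunique()
    common_items = counts[counts >= 2].index.tolist()
    if len(common_items) < 2:
        raise LinkingError("groups share fewer than two common items")
    long = long[long["item"].isin(common_items)]

    items = sorted(common_items, key=str)
    item_ix = {it: j for j, it in enumerate(items)}
    group_ix = {g: j for j, g in enumerate(g for g in groups if g != reference)}
    n_obs = len(long)
    n_items = len(items)
    n_free = len(group_ix)

    # stage 1: log a_ic = log a_i + log nu1_c, reference log nu1 = 0
    x1 = np.zeros((n_obs, n_items + n_free))
    y1 = np.log(long["a"].to_numpy())
    for k, (_, r) in enumerate(long.iterrows()):
        x1[k, item_ix[r["item"]]] = 1.0
        if r["group"] != reference:
            x1[k, n_items + group_ix[r["group"]]] = 1.0
    sol1, *_ = np.linalg.lstsq(x1, y1, rcond=None)
    log_a = sol1[:n_items]
    log_nu1 = {g: (0.0 if g == reference else float(sol1[n_items + group_ix[g]]))
               for g in groups}
    nu1 = {g: float(np.exp(v)) for g, v in log_nu1.items()}

    # stage 2: b_i - nu0_c - nu1_c b_ic = 0, reference nu0 = 0
    x2 = np.zeros((n_obs, n_items + n_free))
    y2 = np.empty(n_obs)
    for k, (_, r) in enumerate(long.iterrows()):
        x2[k, item_ix[r["item"]]] = 1.0
        if r["group"] != reference:
            x2[k, n_items + group_ix[r["group"]]] = -1.0
        y2[k] = nu1[r["group"]] * r["b"]
    sol2, *_ = np.linalg.lstsq(x2, y2, rcond=None)
    b_common = sol2[:n_items]
    nu0 = {g: (0.0 if g == reference else float(sol2[n_items + group_ix[g]]))
           for g in groups}

    return LinkResult(
        groups=groups,
        nu0=nu0,
        nu1=nu1,
        common_a=pd.Series(np.exp(log_a), index=items, name="a"),
        common_b=pd.Series(b_common, index=items, name="b"),
    )


def link_to_truth(estimated, truth) -> tuple[float, float]:
    """Link estimated item parameters to the truth; return (mean, SD).

    ``estimated`` is a table/(a, b) pair on the standardized estimation
    metric; ``truth`` is an :class:`~irtmiss.datagen.ItemBank` or table of
    the generating parameters.  Truth is the reference group, so the
    returned (nu0, nu1) are the estimated population mean and SD on the
    generating metric.
    """
    if hasattr(truth, "discrimination"):
        truth_tab = pd.DataFrame(
            {"item": truth.item_id, "a": truth.discrimination, "b": truth.difficulty}
        )
    else:
        truth_tab = _as_table(truth)
    est_tab = _as_table(estimated)
    if len(est_tab) != len(truth_tab):
        raise LinkingError("estimated and true banks must cover the same items")
    est_tab = est_tab.copy()
    est_tab["item"] = truth_tab["item"].to_numpy()
    res = haberman_link({"truth": truth_tab, "estimate": est_tab}, reference="truth")
    return res.nu0["estimate"], res.nu1["estimate"]


def to_reporting_metric(
    group_means,
    group_sds,
    group_weights=None,
    target_mean: float = 500.0,
    target_sd: float = 100.0,
):
    """Affine map so the pooled population has mean 500 and SD 100.

    The pooled variance is the weighted mean of sigma_c^2 + (mu_c - mu)^2
    (within plus between).  One common map is applied to every group, so
    group orderings and distances in SD units are preserved.
    """
    mu = np.asarray(group_means, dtype=float)
    sd = np.asarray(group_sds, dtype=float)
    w = (np.ones_like(mu) if group_weights is None
         else np.asarray(group_weights, dtype=float))
    if np.any(w < 0) or w.sum() <= 0:
        raise LinkingError("group weights must be nonnegative and not all zero")
    w = w / w.sum()
    pooled_mean = float(w @ mu)
    pooled_var = float(w @ (sd**2 + (mu - pooled_mean) ** 2))
    if pooled_var <= 0:
        raise LinkingError("zero pooled variance; reporting transform undefined")
    scale = target_sd / np.sqrt(pooled_var)
    new_means = target_mean + scale * (mu - pooled_mean)
    new_sds = scale * sd
    return new_means, new_sds
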