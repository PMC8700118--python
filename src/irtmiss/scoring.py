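"""Deterministic pre-scaling treatments of missing responses.

These operations produce a scored matrix (entries 0, 1, a fraction in
(0, 1), or missing) that a unidimensional 2PL is then fitted to.  The
treatments correspond to the "response indicators unmodeled" family:
scoring as wrong, partially-correct (guessing) scoring of multiple-choice
items, ignoring missing responses, and missingness-proportion covariates
for the latent background model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import ItemBank, ResponseData

__all__ = [
    "ScoredMatrix",
    "MissingClassification",
    "score_as_wrong",
    "score_ignored",
    "score_partially_correct",
    "classify_not_reached",
    "missing_covariates",
]

logger = logging.getLogger(__name__)

OBSERVED, OMITTED, NOT_REACHED, NOT_ADMINISTERED = (
    "observed",
    "omitted",
    "not_reached",
    "not_administered",
)


@dataclass
class ScoredMatrix:
    """Persons x items matrix of scored responses with a treatment label."""

    values: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("scored entries must lie in [0, 1] or be missing")


@dataclass
class MissingClassification:
    """Per-cell labels partitioning all cells of the response matrix."""

    labels: np.ndarray  # persons x items array of strings

    def to_frame(self, item_ids=None) -> pd.DataFrame:
        n, m = self.labels.shape
        items = np.arange(m) if item_ids is None else np.asarray(item_ids)
        return pd.DataFrame(
            {
                "person": np.repeat(np.arange(n), m),
                "item": np.tile(items, n),
                "label": self.labels.ravel(),
            }
        )


def classify_not_reached(
    data: ResponseData, item_order: np.ndarray | None = None
) -> MissingClassification:
    """Label each cell observed / omitted / not_reached / not_administered.

    Not-reached cells are the maximal trailing run of consecutive missing
    cells in a person's administered item sequence; every other missing
    cell is an omission.  Without an explicit ``item_order`` the column
    order is taken as the booklet order.
    """
    if item_order is None:
        order = np.arange(data.n_items)
        logger.info("no item order given; assuming column order is booklet order")
    else:
        order = np.asarray(item_order)
    labels = np.full(data.observed.shape, OBSERVED, dtype=object)
    adm = data.administered == 1
    miss = (data.indicators == 0) & adm
    labels[~adm] = NOT_ADMINISTERED
    labels[miss] = OMITTED
    for p in range(data.n_persons):
        seq = order[adm[p, order]]  # administered items in booklet order
        for i in seq[::-1]:
            if miss[p, i]:
                labels[p, i] = NOT_REACHED
            else:
                break
    return MissingClassification(labels=labels)


def score_as_wrong(
    data: ResponseData,
    which: str = "all",
    classification: MissingClassification | None = None,
) -> ScoredMatrix:
    """Score missing cells as 0.

    ``which="all"`` scores every missing response as wrong; with
    ``which="omitted_only"`` not-reached cells stay missing (and are
    ignored by the scaling model).
    """
    if which not in ("all", "omitted_only"):
        raise ValueError(f"unknown scope {which!r}")
    out = data.observed.copy()
    adm = data.administered == 1
    miss = (data.indicators == 0) & adm
    if which == "all":
        out[miss] = 0.0
        return ScoredMatrix(out, "UW")
    if classification is None:
        classification = classify_not_reached(data)
    omitted = classification.labels == OMITTED
    out[miss & omitted] = 0.0
    return ScoredMatrix(out, "UN1")


def score_ignored(data: ResponseData) -> ScoredMatrix:
    """Leave missing cells missing; only observed responses enter the likelihood."""
    return ScoredMatrix(data.observed.copy(), "UO1")


def score_partially_correct(data: ResponseData, bank: ItemBank) -> ScoredMatrix:
    """Missing MC cells become the guessing probability 1/K_i, missing CR cells 0."""
    is_mc = bank.format == "MC"
    if np.any(is_mc & ~np.isfinite(bank.n_options)):
        raise ValueError("every MC item needs n_options for partially-correct scoring")
    out = data.observed.copy()
    adm = data.administered == 1
    miss = (data.indicators == 0) & adm
    frac = np.where(is_mc, 1.0 / bank.n_options, 0.0)
    out[miss] = np.broadcast_to(frac, out.shape)[miss]
    return ScoredMatrix(out, "UP")


def missing_covariates(
    data: ResponseData,
    which: str = "all_missing",
    classification: MissingClassification | None = None,
) -> np.ndarray:
    """Per-person missingness proportion Z_p = 1 - (observed)/(administered).

    ``which="all_missing"`` counts every missing cell, ``which="not_reached"``
    only the trailing not-reached block.  Z_p feeds the latent background
    model as a proxy for the response propensity.
    """
    if which not in ("all_missing", "not_reached"):
        raise ValueError(f"unknown missing class {which!r}")
    adm = (data.administered == 1).astype(float)
    n_adm = adm.sum(axis=1)
    if np.any(n_adm == 0):
        raise ValueError("a person with zero administered items has no covariate")
    miss = ((data.indicators == 0) & (data.administered == 1)).astype(float)
    if which == "not_reached":
        if classification is None:
            classification = classify_not_reached(data)
        miss = miss * (classification.labels == NOT_REACHED)
    return miss.sum(axis=1) / n_adm
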