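"""Synthetic data from the Mislevy-Wu data-generating process.

Abilities theta and response propensities xi are bivariate normal with
Var(theta) = 1.  Item responses follow the 2PL model

    P(X_pi = 1 | theta_p) = psi(a_i (theta_p - b_i)),

with psi the standard logistic distribution function, and response
indicators follow

    P(R_pi = 1 | X_pi, theta_p, xi_p) = psi(xi_p - beta_i - delta_i X_pi).

delta_i = 0 gives latent-ignorable missingness; a large negative delta_i
(conventionally -10) means only incorrect responses can go missing.  The
common missingness intercept beta is calibrated numerically so that the
expected missing proportion hits a target rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "ItemBank",
    "LatentDraws",
    "ResponseData",
    "TruthRecord",
    "DesignCell",
    "make_item_bank",
    "draw_latents",
    "simulate_complete",
    "simulate_indicators",
    "expected_missing_rate",
    "calibrate_beta",
    "generate_dataset",
    "write_response_csv",
    "read_response_csv",
    "write_item_bank_csv",
    "read_item_bank_csv",
]


class InvalidDesignError(ValueError):
    """Raised for structurally impossible design requests."""


class CalibrationError(RuntimeError):
    """Raised when no beta in the search bracket attains the target rate."""


@dataclass
class ItemBank:
    """Per-item measurement and missingness parameters.

    ``discrimination`` (a_i) and ``difficulty`` (b_i) parametrize the 2PL
    response function; ``beta`` and ``delta`` parametrize the response
    indicator model.  ``n_options`` (K_i) is defined only for
    multiple-choice (MC) items and drives partially-correct scoring.
    """

    item_id: np.ndarray
    discrimination: np.ndarray
    difficulty: np.ndarray
    format: np.ndarray
    n_options: np.ndarray  # NaN for CR items
    beta: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.item_id = np.asarray(self.item_id)
        for name in ("discrimination", "difficulty", "beta", "delta", "n_options"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.format = np.asarray(self.format, dtype=object)
        if np.any(self.discrimination <= 0):
            raise InvalidDesignError("item discriminations must be positive")
        if not np.all(np.isfinite(self.difficulty)):
            raise InvalidDesignError("item difficulties must be finite")
        is_mc = self.format == "MC"
        if np.any(is_mc & ~(self.n_options >= 2)):
            raise InvalidDesignError("MC items need n_options >= 2")
        if np.any(~is_mc & np.isfinite(self.n_options)):
            raise InvalidDesignError("n_options is defined only for MC items")

    @property
    def n_items(self) -> int:
        return len(self.item_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_id,
                "format": self.format,
                "n_options": self.n_options,
                "a": self.discrimination,
                "b": self.difficulty,
                "beta": self.beta,
                "delta": self.delta,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemBank":
        return cls(
            item_id=df["item_id"].to_numpy(),
            discrimination=df["a"].to_numpy(float),
            difficulty=df["b"].to_numpy(float),
            format=df["format"].to_numpy(object),
            n_options=df["n_options"].to_numpy(float),
            beta=df["beta"].to_numpy(float),
            delta=df["delta"].to_numpy(float),
        )


@dataclass
class LatentDraws:
    """Sampled person abilities (theta) and response propensities (xi)."""

    theta: np.ndarray
    xi: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if self.theta.shape != self.xi.shape:
            raise InvalidDesignError("theta and xi must have equal length")


@dataclass
class ResponseData:
    """Observed response matrix plus response indicators.

    ``observed`` holds 0/1 with NaN as the missing marker; ``indicators``
    is R_pi (1 = observed); ``administered`` masks the booklet design
    (all ones for a linear fixed design).  Cells outside the administered
    mask are excluded from every likelihood.
    """

    observed: np.ndarray
    indicators: np.ndarray
    administered: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.indicators = np.asarray(self.indicators, dtype=np.int8)
        self.administered = np.asarray(self.administered, dtype=np.int8)
        adm = self.administered == 1
        missing = np.isnan(self.observed)
        if np.any((self.indicators == 1) & missing & adm):
            raise InvalidDesignError("indicator 1 requires an observed value")
        if np.any((self.indicators == 0) & ~missing & adm):
            raise InvalidDesignError("indicator 0 requires a missing value")

    @property
    def n_persons(self) -> int:
        return self.observed.shape[0]

    @property
    def n_items(self) -> int:
        return self.observed.shape[1]

    def missing_rate(self) -> float:
        """Realized proportion of missing cells within the administered mask."""
        adm = self.administered == 1
        return float(np.mean(self.indicators[adm] == 0))


@dataclass
class TruthRecord:
    """Provenance of one simulated dataset (truth has M = 0, SD = 1)."""

    bank: ItemBank
    correlation: float
    sd_xi: float
    target_missing_rate: float
    seed: int
    n_persons: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "correlation": self.correlation,
            "sd_xi": self.sd_xi,
            "target_missing_rate": self.target_missing_rate,
            "seed": self.seed,
            "n_persons": self.n_persons,
            "bank": self.bank.to_frame().to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class DesignCell:
    """One cell of the simulation design."""

    n_persons: int = 1500
    n_items: int = 20
    delta: float = 0.0
    missing_rate: float = 0.10
    correlation: float = 0.5
    sd_xi: float = 1.0
    difficulty_range: tuple[float, float] = (-2.0, 2.0)
    discrimination: float = 1.0


def make_item_bank(
    n_items: int,
    difficulty_range: Sequence[float] = (-2.0, 2.0),
    discrimination: float = 1.0,
    format: str = "CR",
    n_options: int | None = None,
) -> ItemBank:
    """Item bank with difficulties equidistant over a closed interval.

    For ``n_items=20`` on [-2, 2] the first difficulties are -2.000,
    -1.789, -1.579, ...; endpoints are always included.
    """
    if n_items < 2:
        raise InvalidDesignError("need at least 2 items for an equidistant bank")
    lo, hi = difficulty_range
    b = np.linspace(lo, hi, n_items)
    fmt = np.array([format] * n_items, dtype=object)
    k = np.full(n_items, np.nan)
    if format == "MC":
        if n_options is None:
            raise InvalidDesignError("MC bank requires n_options")
        k[:] = n_options
    return ItemBank(
        item_id=np.array([f"I{i + 1:02d}" for i in range(n_items)]),
        discrimination=np.full(n_items, float(discrimination)),
        difficulty=b,
        format=fmt,
        n_options=k,
        beta=np.zeros(n_items),
        delta=np.zeros(n_items),
    )


def draw_latents(
    n: int,
    correlation: float,
    sd_xi: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> LatentDraws:
    """Bivariate-normal draws with Var(theta) = 1 and SD(xi) = ``sd_xi``."""
    if not -1.0 < correlation < 1.0:
        raise InvalidDesignError("|correlation| must be < 1")
    if n < 1:
        raise InvalidDesignError("need n >= 1 draws")
    rng = np.random.default_rng(rng)
    z = rng.standard_normal((n, 2))
    theta = z[:, 0]
    xi = sd_xi * (correlation * z[:, 0] + np.sqrt(1.0 - correlation**2) * z[:, 1])
    return LatentDraws(theta=theta, xi=xi)


def simulate_complete(
    latents: LatentDraws,
    bank: ItemBank,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Complete 2PL response matrix; Bernoulli given theta, independent across items."""
    rng = np.random.default_rng(rng)
    eta = bank.discrimination[None, :] * (latents.theta[:, None] - bank.difficulty[None, :])
    p = expit(eta)
    return (rng.random(p.shape) < p).astype(np.int8)


def simulate_indicators(
    complete_x: np.ndarray,
    latents: LatentDraws,
    bank: ItemBank,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Response indicators R_pi ~ Bernoulli(psi(xi - beta_i - delta_i X_pi))."""
    rng = np.random.default_rng(rng)
    x = np.asarray(complete_x, dtype=float)
    if np.any(np.isnan(x)):
        raise InvalidDesignError("complete response matrix must not contain missing cells")
    eta = latents.xi[:, None] - bank.beta[None, :] - bank.delta[None, :] * x
    p = expit(eta)
    return (rng.random(p.shape) < p).astype(np.int8)


def _gauss_hermite_2d(correlation: float, sd_xi: float, n_nodes: int = 41):
    """Nodes/weights for E over (theta, xi): theta std normal, xi correlated."""
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    x = np.sqrt(2.0) * z
    w = w / np.sqrt(np.pi)
    t = np.repeat(x, n_nodes)
    z2 = np.tile(x, n_nodes)
    xi = sd_xi * (correlation * t + np.sqrt(1.0 - correlation**2) * z2)
    ww = np.repeat(w, n_nodes) * np.tile(w, n_nodes)
    return t, xi, ww


def expected_missing_rate(
    beta: float,
    delta: float,
    correlation: float,
    bank: ItemBank,
    sd_xi: float = 1.0,
    n_nodes: int = 41,
) -> float:
    """Expected missing proportion under the generator, by 2-D quadrature.

    Averages 1 - psi(xi-beta) (1-P_i(theta)) - psi(xi-beta-delta) P_i(theta)
    over items and the bivariate latent distribution (41-point
    Gauss-Hermite per dimension).
    """
    t, xi, w = _gauss_hermite_2d(correlation, sd_xi, n_nodes)
    p = expit(bank.discrimination[:, None] * (t[None, :] - bank.difficulty[:, None]))
    q0 = expit(xi - beta)[None, :]
    q1 = expit(xi - beta - delta)[None, :]
    miss = 1.0 - q0 * (1.0 - p) - q1 * p
    return float(np.mean(miss @ w))


def calibrate_beta(
    delta: float,
    target_rate: float,
    correlation: float,
    bank: ItemBank,
    sd_xi: float = 1.0,
    bracket: tuple[float, float] = (-12.0, 12.0),
    tol: float = 1e-4,
) -> float:
    """Common beta whose expected missing proportion equals ``target_rate``.

    The rate is strictly increasing in beta, so the root in the bracket is
    unique; it is located with Brent's method and verified to ``tol``.
    """
    if not 0.0 < target_rate < 1.0:
        raise CalibrationError("target rate must lie strictly between 0 and 1")

    def f(beta: float) -> float:
        return expected_missing_rate(beta, delta, correlation, bank, sd_xi) - target_rate

    lo, hi = bracket
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(f"no beta in {bracket} attains rate {target_rate}")
    beta = brentq(f, lo, hi, xtol=1e-10)
    if abs(f(beta)) > tol:
        raise CalibrationError("calibration did not reach the rate tolerance")
    return float(beta)


def generate_dataset(
    config: DesignCell,
    seed: int,
    return_complete: bool = False,
):
    """Full pipeline: bank, beta calibration, latents, responses, indicators, mask.

    One master seed; sub-streams for latents, responses and indicators are
    derived deterministically, so the same seed reproduces the dataset
    bit for bit.  With ``return_complete`` the pre-masking response matrix
    is appended to the return tuple (for complete-data reference fits).
    """
    bank = make_item_bank(
        config.n_items, config.difficulty_range, config.discrimination
    )
    beta = calibrate_beta(
        config.delta, config.missing_rate, config.correlation, bank, config.sd_xi
    )
    bank.beta[:] = beta
    bank.delta[:] = config.delta

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(3)
    lat = draw_latents(
        config.n_persons, config.correlation, config.sd_xi, np.random.default_rng(streams[0])
    )
    x = simulate_complete(lat, bank, np.random.default_rng(streams[1]))
    r = simulate_indicators(x, lat, bank, np.random.default_rng(streams[2]))

    observed = x.astype(float)
    observed[r == 0] = np.nan
    data = ResponseData(
        observed=observed,
        indicators=r,
        administered=np.ones_like(r),
    )
    truth = TruthRecord(
        bank=bank,
        correlation=config.correlation,
        sd_xi=config.sd_xi,
        target_missing_rate=config.missing_rate,
        seed=seed if isinstance(seed, int) else -1,
        n_persons=config.n_persons,
    )
    if return_complete:
        return data, truth, x
    return data, truth


# ---------------------------------------------------------------------------
# CSV round trips (0/1/NA cells, header = item ids)

def write_response_csv(data: ResponseData, bank: ItemBank, path: str | Path) -> None:
    df = pd.DataFrame(data.observed, columns=bank.item_id)
    df.to_csv(path, index=False, na_rep="NA")


def read_response_csv(path: str | Path) -> ResponseData:
    df = pd.read_csv(path, na_values=["NA"])
    obs = df.to_numpy(float)
    r = (~np.isnan(obs)).astype(np.int8)
    return ResponseData(observed=obs, indicators=r, administered=np.ones_like(r))


def write_item_bank_csv(bank: ItemBank, path: str | Path) -> None:
    bank.to_frame().to_csv(path, index=False, na_rep="NA")


def read_item_bank_csv(path: str | Path) -> ItemBank:
    return ItemBank.from_frame(pd.read_csv(path, na_values=["NA"]))
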