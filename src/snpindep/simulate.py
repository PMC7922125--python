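"""Generative model for a dependent SNP pair and an interaction-driven trait.

Two loci are simulated: X1 from a binomial model with carrier probability
``p1``, and X2 from a logistic model conditional on X1,

    logit P(X2 = 1) = gamma0 + gamma1 * X1,

so that ``gamma1 != 0`` induces correlation between the two SNPs.  The
continuous trait is then

    Y = beta0 + beta1*X1 + beta2*X2 + beta_I*X1*X2 + eps,   eps ~ N(0, sigma^2),

where ``beta_I`` is the epistatic (SNP-by-SNP interaction) effect.  Both a
binary genetic coding (dominant/recessive carrier indicator, values 0/1) and
an additive coding (minor-allele count, values 0/1/2) are supported.  Under
the additive coding X2 is drawn as the sum of two conditionally independent
allele draws, each with per-allele success probability
``logistic(gamma0 + gamma1*X1)`` — a Hardy-Weinberg-like extension that
reduces to the binary rule on the binary domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .exceptions import InvalidParameterError

__all__ = [
    "SimulationParams",
    "SimulatedDataset",
    "draw_x1",
    "draw_x2_given_x1",
    "draw_trait",
    "simulate_dataset",
]

_CODINGS = ("binary", "additive")


@dataclass
class SimulationParams:
    """All generative constants of one simulation replicate.

    Parameters
    ----------
    n : int
        Subjects per replicate.
    p1 : float
        Carrier probability (binary coding) or allele frequency (additive
        coding) of X1; strictly inside (0, 1).
    gamma0, gamma1 : float
        Intercept and slope, in log-odds units, of the logistic model for
        X2 given X1.
    beta0, beta1, beta2, beta_I : float
        Trait-model coefficients: intercept, X1 main effect, X2 main
        effect, and the X1*X2 interaction.
    sigma : float
        Residual standard deviation of the trait; ``sigma = 0`` is allowed
        as an exact-predictor mode for closed-form checks.
    coding : {"binary", "additive"}
        Genetic coding shared by both SNPs.
    seed : int
        Root seed for reproducibility.
    """

    n: int = 1000
    p1: float = 0.5
    gamma0: float = 0.0
    gamma1: float = 0.3
    beta0: float = 0.0
    beta1: float = 0.3
    beta2: float = 0.3
    beta_I: float = 0.3
    sigma: float = 1.0
    coding: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise InvalidParameterError(f"n must be a positive integer, got {self.n}")
        self.n = int(self.n)
        if not 0.0 < self.p1 < 1.0:
            raise InvalidParameterError(f"p1 must lie strictly in (0, 1), got {self.p1}")
        if self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")
        if self.coding not in _CODINGS:
            raise InvalidParameterError(
                f"coding must be one of {_CODINGS}, got {self.coding!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedDataset:
    """One replicate's genotype pair and trait, all of equal length."""

    x1: np.ndarray
    x2: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1)
        self.x2 = np.asarray(self.x2)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.x1) == len(self.x2) == len(self.y)):
            raise InvalidParameterError("x1, x2, y must have equal lengths")

    @property
    def n(self) -> int:
        return len(self.y)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x1": self.x1, "x2": self.x2, "y": self.y})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_coding(coding: str) -> None:
    if coding not in _CODINGS:
        raise InvalidParameterError(f"coding must be one of {_CODINGS}, got {coding!r}")


def draw_x1(n: int, p1: float, coding: str = "binary", rng=None) -> np.ndarray:
    """Draw the first SNP's genotype vector.

    Binary coding gives independent Bernoulli(p1) carrier indicators;
    additive coding gives Binomial(2, p1) allele counts.
    """
    if int(n) != n or n < 1:
        raise InvalidParameterError(f"n must be a positive integer, got {n}")
    if not 0.0 < p1 < 1.0:
        raise InvalidParameterError(f"p1 must lie strictly in (0, 1), got {p1}")
    _check_coding(coding)
    rng = np.random.default_rng(rng)
    if coding == "binary":
        return (rng.random(int(n)) < p1).astype(np.int8)
    return rng.binomial(2, p1, size=int(n)).astype(np.int8)


def draw_x2_given_x1(
    x1: np.ndarray, gamma0: float, gamma1: float, coding: str = "binary", rng=None
) -> np.ndarray:
    """Draw the second SNP conditional on the first via the logistic model.

    Each subject's success probability is ``expit(gamma0 + gamma1 * x1)``;
    the binary coding draws one Bernoulli indicator per subject, the
    additive coding sums two conditionally independent allele draws.
    """
    _check_coding(coding)
    x1 = np.asarray(x1)
    hi = 1 if coding == "binary" else 2
    if x1.size and (x1.min() < 0 or x1.max() > hi):
        raise InvalidParameterError(f"x1 values outside the {coding} coding domain")
    rng = np.random.default_rng(rng)
    p = expit(gamma0 + gamma1 * x1.astype(float))
    if coding == "binary":
        return (rng.random(x1.shape) < p).astype(np.int8)
    return rng.binomial(2, p).astype(np.int8)


def draw_trait(
    x1: np.ndarray,
    x2: np.ndarray,
    beta0: float,
    beta1: float,
    beta2: float,
    beta_I: float,
    sigma: float,
    rng=None,
) -> np.ndarray:
    """Draw the continuous trait from the interaction model.

    ``y = beta0 + beta1*x1 + beta2*x2 + beta_I*x1*x2 + N(0, sigma^2)``;
    with ``sigma = 0`` the linear predictor is returned exactly.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise InvalidParameterError("x1 and x2 must have the same shape")
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    mu = beta0 + beta1 * x1 + beta2 * x2 + beta_I * x1 * x2
    if sigma == 0:
        return mu
    rng = np.random.default_rng(rng)
    return mu + rng.normal(0.0, sigma, size=x1.shape)


def simulate_dataset(params: SimulationParams, rng=None) -> SimulatedDataset:
    """Simulate one replicate: X1, then X2 | X1, then Y | (X1, X2).

    Deterministic given ``params.seed`` when no generator is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    x1 = draw_x1(params.n, params.p1, params.coding, rng)
    x2 = draw_x2_given_x1(x1, params.gamma0, params.gamma1, params.coding, rng)
    y = draw_trait(
        x1, x2, params.beta0, params.beta1, params.beta2, params.beta_I, params.sigma, rng
    )
    return SimulatedDataset(x1=x1, x2=x2, y=y)
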