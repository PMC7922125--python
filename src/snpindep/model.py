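"""Model/results interface for judging independence of two SNP signals.

`SignalIndependenceModel` holds one trait vector, two genotype vectors and
optional covariates/weights; `fit()` runs the marginal, conditional and
interaction regressions and returns a `SignalIndependenceResults` carrying
the three Wald tests, from which the five-way outcome scenario at any
significance level can be read off.
"""

from __future__ import annotations

import numpy as np

from . import regression
from .exceptions import InvalidParameterError
from .scenario import Scenario, classify
from .simulate import SimulatedDataset

__all__ = ["SignalIndependenceModel", "SignalIndependenceResults"]


class SignalIndependenceModel:
    """Trait ~ two SNPs (+ covariates), fitted three nested ways.

    Parameters
    ----------
    y : array-like
        Continuous trait.
    x1 : array-like
        Index SNP (the signal whose independence is questioned).
    x2 : array-like
        Conditioning SNP.
    covariates : 2-D array or DataFrame, optional
        Numeric adjustment columns (categoricals pre-expanded to indicators).
    weights : array-like, optional
        Positive per-subject weights for weighted least squares.
    """

    def __init__(self, y, x1, x2, covariates=None, weights=None, snp_names=("x1", "x2")):
        self.y = np.asarray(y, dtype=float)
        self.x1 = np.asarray(x1, dtype=float)
        self.x2 = np.asarray(x2, dtype=float)
        n = len(self.y)
        if len(self.x1) != n or len(self.x2) != n:
            raise InvalidParameterError("y, x1, x2 must have equal lengths")
        self.covariates = covariates
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.snp_names = tuple(snp_names)

    @classmethod
    def from_dataframe(
        cls, df, trait, index_snp, other_snp, covariates=(), weights=None
    ) -> "SignalIndependenceModel":
        """Build from named columns of a DataFrame."""
        cov = df[list(covariates)] if covariates else None
        w = df[weights].to_numpy() if weights else None
        return cls(
            df[trait].to_numpy(),
            df[index_snp].to_numpy(),
            df[other_snp].to_numpy(),
            covariates=cov,
            weights=w,
            snp_names=(index_snp, other_snp),
        )

    @classmethod
    def from_dataset(cls, data: SimulatedDataset, covariates=None, weights=None):
        return cls(data.y, data.x1, data.x2, covariates=covariates, weights=weights)

    def fit(self) -> "SignalIndependenceResults":
        data = SimulatedDataset(x1=self.x1, x2=self.x2, y=self.y)
        r0 = regression.algorithm0(data, self.covariates, self.weights)
        r1 = regression.algorithm1(data, self.covariates, self.weights)
        r2 = regression.algorithm2(data, self.covariates, self.weights)
        return SignalIndependenceResults(self, r0, r1, r2)


class SignalIndependenceResults:
    """Marginal, conditional and interaction tests for one SNP pair."""

    def __init__(self, model, alg0, alg1, alg2):
        self.model = model
        self.alg0 = alg0
        self.alg1 = alg1
        self.alg2 = alg2

    @property
    def pvalues(self) -> dict:
        return {
            "marginal": self.alg0.p_target,
            "conditional": self.alg1.p_target,
            "interaction": self.alg2.p_target,
        }

    def scenario(self, alpha: float = 5e-8) -> Scenario:
        """Five-way outcome class at significance level `alpha`."""
        return classify(
            np.nan if self.alg0.failed else self.alg0.p_target,
            np.nan if self.alg1.failed else self.alg1.p_target,
            np.nan if self.alg2.failed else self.alg2.p_target,
            alpha,
        )

    def summary(self, alpha: float = 5e-8) -> str:
        n1, n2 = self.model.snp_names
        lines = [
            "Signal-independence analysis",
            "=" * 64,
            f"index SNP: {n1}   conditioning SNP: {n2}   "
            f"n = {len(self.model.y)}",
            f"{'model':<14}{'term':<10}{'coef':>10}{'se':>10}{'p-value':>12}",
            "-" * 64,
        ]
        rows = [
            ("marginal", n1, self.alg0),
            ("conditional", n1, self.alg1),
            ("interaction", f"{n1}:{n2}", self.alg2),
        ]
        for label, term, r in rows:
            if r.failed:
                lines.append(f"{label:<14}{term:<10}{'-- failed: ' + r.failure_reason}")
            else:
                lines.append(
                    f"{label:<14}{term:<10}{r.coef_target:>10.4f}"
                    f"{r.se_target:>10.4f}{r.p_target:>12.3g}"
                )
        lines.append("-" * 64)
        lines.append(f"scenario at alpha={alpha:g}: {self.scenario(alpha)}")
        return "\n".join(lines)
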