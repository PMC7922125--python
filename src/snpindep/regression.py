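"""Weighted least squares with Wald tests, and the three nested association fits.

The three fits used to judge whether two SNP signals are independent:

* Algorithm 0 — marginal: ``E[Y] = d0 + d1*X1``, testing ``H0: d1 = 0``;
* Algorithm 1 — conditional: ``E[Y] = a0 + a1*X1 + a2*X2``, testing
  ``H0: a1 = 0`` (does X1 survive conditioning on X2?);
* Algorithm 2 — interaction: ``E[Y] = f0 + f1*X1 + f2*X2 + fI*X1*X2``,
  testing ``H0: fI = 0`` (is there epistasis?).

Each may additionally adjust for a numeric covariate matrix (categorical
covariates must be expanded to indicators upstream) and per-subject weights.

Wald statistics are referred to the t distribution with residual degrees of
freedom — standard least-squares practice; at the simulation sample sizes it
is indistinguishable from the normal reference.  Exact fits (zero residual
variance) report p = 0 with an explicit flag so downstream scenario
classification remains total, and rank-deficient designs drop aliased
columns, detected at a relative singular-value tolerance of 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy import stats

from .exceptions import DegenerateDesignError, InvalidParameterError

__all__ = [
    "FitResult",
    "AlgorithmResult",
    "fit_linear",
    "algorithm0",
    "algorithm1",
    "algorithm2",
]

RANK_TOL = 1e-10
"""Relative tolerance on the design's pivoted-QR diagonal for rank detection."""

_EXACT_FIT_RTOL = 1e-12


@dataclass
class FitResult:
    """Per-term output of one (weighted) least-squares fit.

    Aliased (inestimable) terms carry NaN in ``coef``/``se``/``stat``/
    ``pvalue`` and True in ``aliased``.
    """

    term_names: list
    coef: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    pvalue: np.ndarray
    df_resid: int
    sigma2_hat: float
    rank_deficient: bool
    aliased: np.ndarray
    exact_fit: bool = False
    nobs: int = 0

    def __getitem__(self, term: str) -> dict:
        i = self.term_names.index(term)
        return {
            "coef": self.coef[i],
            "se": self.se[i],
            "stat": self.stat[i],
            "pvalue": self.pvalue[i],
            "aliased": bool(self.aliased[i]),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "term": self.term_names,
                "coef": self.coef,
                "se": self.se,
                "stat": self.stat,
                "pvalue": self.pvalue,
                "aliased": self.aliased,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class AlgorithmResult:
    """One algorithm's fit plus the Wald test of its null hypothesis."""

    algorithm: int
    target_term: str
    p_target: float
    coef_target: float
    se_target: float
    fit: FitResult | None
    failed: bool = False
    failure_reason: str = ""


def _greedy_estimable(Xw: np.ndarray, rank: int) -> np.ndarray:
    """Select `rank` estimable columns scanning left to right."""
    smax = np.linalg.norm(Xw, 2)
    tol = RANK_TOL * (smax if smax > 0 else 1.0)
    kept: list[int] = []
    for j in range(Xw.shape[1]):
        cand = kept + [j]
        if np.linalg.matrix_rank(Xw[:, cand], tol=tol) > len(kept):
            kept.append(j)
        if len(kept) == rank:
            break
    return np.asarray(kept, dtype=int)


def fit_linear(y, design, weights=None, term_names=None) -> FitResult:
    """Weighted least squares via pivoted QR with aliased-term handling.

    Coefficients minimise the weighted residual sum of squares; standard
    errors come from ``sigma2_hat * (X' W X)^{-1}`` restricted to the
    estimable columns with ``sigma2_hat = weighted RSS / df_resid``; Wald
    p-values are two-sided from t(df_resid).  Weights are invariant to a
    positive rescaling.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n == 0:
        raise InvalidParameterError("empty design: zero rows")
    if len(y) != n:
        raise InvalidParameterError(f"design has {n} rows but y has {len(y)}")
    if term_names is None:
        term_names = [f"x{j}" for j in range(k)]
    term_names = list(term_names)
    if len(term_names) != k:
        raise InvalidParameterError("term_names length does not match design columns")

    if weights is None:
        sw = np.ones(n)
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if len(w) != n or np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise InvalidParameterError("weights must be finite, positive, length n")
        # scale invariance: normalise so sum(w) = n
        w = w * (n / w.sum())
        sw = np.sqrt(w)

    Xw = X * sw[:, None]
    yw = y * sw

    # pivoted QR: rank and the set of estimable columns
    Q, R, piv = linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = RANK_TOL * (diag[0] if diag.size and diag[0] > 0 else 1.0)
    rank = int(np.sum(diag > tol))
    if rank == 0:
        raise DegenerateDesignError("design has rank zero")
    if rank == k:
        kept = np.arange(k)
    else:
        # earlier columns win ties so the intercept is never the aliased one
        kept = _greedy_estimable(Xw, rank)
    aliased = np.ones(k, dtype=bool)
    aliased[kept] = False

    df_resid = n - rank
    if df_resid <= 0:
        raise DegenerateDesignError(
            f"no residual degrees of freedom (n={n}, rank={rank})"
        )

    Xk = Xw[:, kept]
    coef_k, _, _, _ = np.linalg.lstsq(Xk, yw, rcond=None)
    resid = yw - Xk @ coef_k
    rss = float(resid @ resid)
    tss = float(yw @ yw)
    sigma2 = rss / df_resid
    exact_fit = rss <= _EXACT_FIT_RTOL * max(1.0, tss)

    XtX_inv = np.linalg.inv(Xk.T @ Xk)

    coef = np.full(k, np.nan)
    se = np.full(k, np.nan)
    stat = np.full(k, np.nan)
    pval = np.full(k, np.nan)
    coef[kept] = coef_k

    if exact_fit:
        sigma2 = 0.0
        se[kept] = 0.0
        nz = np.zeros(k, dtype=bool)
        nz[kept] = np.abs(coef_k) > 0
        stat[kept] = 0.0
        stat[nz] = np.inf * np.sign(coef[nz])
        pval[kept] = 1.0
        pval[nz] = 0.0
    else:
        se_k = np.sqrt(sigma2 * np.diag(XtX_inv))
        t_k = coef_k / se_k
        p_k = 2.0 * stats.t.sf(np.abs(t_k), df_resid)
        se[kept] = se_k
        stat[kept] = t_k
        pval[kept] = p_k

    return FitResult(
        term_names=term_names,
        coef=coef,
        se=se,
        stat=stat,
        pvalue=pval,
        df_resid=df_resid,
        sigma2_hat=sigma2,
        rank_deficient=rank < k,
        aliased=aliased,
        exact_fit=exact_fit,
        nobs=n,
    )


def _build_design(data, with_x2: bool, with_inter: bool, covariates):
    x1 = np.asarray(data.x1, dtype=float)
    cols = [np.ones_like(x1), x1]
    names = ["const", "x1"]
    if with_x2 or with_inter:
        x2 = np.asarray(data.x2, dtype=float)
        cols.append(x2)
        names.append("x2")
        if with_inter:
            cols.append(x1 * x2)
            names.append("x1:x2")
    X = np.column_stack(cols)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cov_names = getattr(covariates, "columns", None)
        cov_names = (
            [str(c) for c in cov_names]
            if cov_names is not None
            else [f"cov{j}" for j in range(C.shape[1])]
        )
        X = np.column_stack([X, C])
        names = names + cov_names
    return X, names


_SNP_TERMS = ("x1", "x2", "x1:x2")


def _run_algorithm(data, covariates, weights, algorithm: int) -> AlgorithmResult:
    target = {0: "x1", 1: "x1", 2: "x1:x2"}[algorithm]
    X, names = _build_design(
        data, with_x2=algorithm >= 1, with_inter=algorithm == 2, covariates=covariates
    )
    weights = weights if weights is not None else getattr(data, "weights", None)
    try:
        fit = fit_linear(np.asarray(data.y, dtype=float), X, weights, names)
    except DegenerateDesignError as exc:
        return AlgorithmResult(
            algorithm, target, np.nan, np.nan, np.nan, None, True, str(exc)
        )
    # any aliased SNP term (not just the target) voids the algorithm: the
    # conditional/interaction estimate is meaningless under genotype aliasing
    bad = [
        t for t in names if t in _SNP_TERMS and fit.aliased[names.index(t)]
    ]
    if bad:
        return AlgorithmResult(
            algorithm,
            target,
            np.nan,
            np.nan,
            np.nan,
            fit,
            True,
            f"aliased genotype term(s): {', '.join(bad)}",
        )
    t = fit[target]
    return AlgorithmResult(algorithm, target, t["pvalue"], t["coef"], t["se"], fit)


def algorithm0(data, covariates=None, weights=None) -> AlgorithmResult:
    """Marginal fit of the trait on X1; tests whether X1 is associated at all."""
    return _run_algorithm(data, covariates, weights, 0)


def algorithm1(data, covariates=None, weights=None) -> AlgorithmResult:
    """Conditional fit on X1 and X2; tests X1's effect given X2."""
    return _run_algorithm(data, covariates, weights, 1)


def algorithm2(data, covariates=None, weights=None) -> AlgorithmResult:
    """Interaction fit; tests the X1*X2 (epistasis) coefficient."""
    return _run_algorithm(data, covariates, weights, 2)
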