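"""Cohort-mode analysis: covariate-adjusted conditional and interaction tests.

Applies the same three-model machinery to real (or synthetic) cohort data:
for each (index SNP, other SNP) pair it fits the covariate-adjusted
conditional model ``E[Y] = a0 + a1*X1 + a2*X2 + aC'C`` and the interaction
model ``E[Y] = f0 + f1*X1 + f2*X2 + fI*X1*X2 + fC'C`` by (weighted) least
squares, and reports the index SNP's conditional estimate, the interaction
estimate, the other SNP's minor allele frequency, and pairwise LD r^2.

LD is estimated as the squared Pearson correlation of genotype dosages
(composite LD): phase is unavailable from dosages, and under HWE this
reduces to the haplotype-level r^2.  Rows are flagged rather than dropped
when the other SNP is rare (few carriers) or in near-perfect LD with the
index SNP, since both situations make the conditional estimate fragile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidParameterError, UndefinedLDError
from .model import SignalIndependenceModel

__all__ = [
    "CohortTable",
    "GenotypeMatrix",
    "PairwiseResult",
    "read_cohort",
    "maf",
    "ld_r2",
    "conditional_pair_analysis",
    "report_pairs",
]

logger = logging.getLogger(__name__)

MAF_WARN = 0.01
MIN_CARRIERS = 10
R2_WARN = 0.95


@dataclass
class CohortTable:
    """Aligned phenotype side of a cohort: trait, numeric covariates, weights."""

    sample_ids: pd.Index
    trait: np.ndarray
    covariates: pd.DataFrame  # already numeric (indicators expanded)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.trait) != n or len(self.covariates) != n:
            raise DataError("cohort columns are not aligned")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != n or np.any(self.weights <= 0):
                raise DataError("weights must be positive and aligned")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x SNPs) aligned to a CohortTable."""

    sample_ids: pd.Index
    dosages: pd.DataFrame  # columns = SNP ids, values in [0, 2] or NaN

    @property
    def snp_ids(self) -> list:
        return list(self.dosages.columns)

    def dosage(self, snp: str) -> np.ndarray:
        if snp not in self.dosages.columns:
            raise DataError(f"SNP {snp!r} not in genotype matrix")
        return self.dosages[snp].to_numpy(dtype=float)


@dataclass
class PairwiseResult:
    """One report row: LD, MAF and the two adjusted tests for a SNP pair."""

    index_snp: str
    other_snp: str
    maf_other: float
    r2: float
    alg1_beta: float
    alg1_se: float
    alg1_p: float
    alg2_beta: float
    alg2_se: float
    alg2_p: float
    n_used: int
    flags: list = field(default_factory=list)


def maf(g) -> float:
    """Minor allele frequency of a dosage vector: mean(g)/2 folded to <= 0.5."""
    g = np.asarray(g, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise InvalidParameterError("empty dosage vector")
    if g.min() < 0 or g.max() > 2:
        raise InvalidParameterError("dosages must lie in [0, 2]")
    f = float(g.mean() / 2.0)
    return min(f, 1.0 - f)


def ld_r2(g1, g2) -> float:
    """Composite LD: squared Pearson correlation of the two dosage vectors."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise InvalidParameterError("dosage vectors must have equal lengths")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[ok], g2[ok]
    if g1.size < 2 or np.ptp(g1) == 0 or np.ptp(g2) == 0:
        raise UndefinedLDError("LD undefined for a constant genotype vector")
    r = np.corrcoef(g1, g2)[0, 1]
    return min(float(r * r), 1.0)


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected a delimited table with >= 2 columns")
    return df


def _read_vcf(path) -> pd.DataFrame:
    """Dosages from a VCF: DS field when present, else GT hard calls."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        name = var.ID or f"{var.CHROM}:{var.POS}"
        ds = None
        try:
            ds = var.format("DS")
        except Exception:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).ravel()[: len(samples)]
        else:
            d = np.asarray(var.gt_types, dtype=float)
            d[d == 3] = np.nan  # unknown genotype
        cols[name] = d
    if not cols:
        raise DataError(f"no variants found in {path}")
    return pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))


def _read_dosage_table(path) -> pd.DataFrame:
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    df = df.astype(float)
    if np.nanmin(df.to_numpy()) < 0 or np.nanmax(df.to_numpy()) > 2:
        raise DataError(f"{path}: dosages must lie in [0, 2]")
    return df


def expand_categoricals(df: pd.DataFrame, categorical: tuple = ()) -> pd.DataFrame:
    """Dummy-code the named columns, dropping the alphabetically first level."""
    out = []
    for col in df.columns:
        if col in categorical or df[col].dtype == object:
            levels = sorted(df[col].astype(str).unique())
            for lev in levels[1:]:
                out.append(
                    (df[col].astype(str) == lev).astype(float).rename(f"{col}_{lev}")
                )
        else:
            out.append(df[col].astype(float))
    return pd.concat(out, axis=1) if out else pd.DataFrame(index=df.index)


def read_cohort(
    pheno_path,
    geno_path,
    trait: str,
    covariates: tuple = (),
    categorical: tuple = (),
    weight_col: str | None = None,
) -> tuple[CohortTable, GenotypeMatrix]:
    """Load and inner-join phenotype and genotype files on sample id.

    The phenotype file is delimited text whose first column is the sample
    id; genotypes come from a VCF (``.vcf``) or a delimited samples-by-SNPs
    dosage table.  Categorical covariates are expanded to indicator
    columns (reference level = first alphabetically); rows with a missing
    trait, covariate or weight are dropped (complete-case) with a logged
    count.
    """
    pheno = _read_table(pheno_path)
    pheno = pheno.set_index(pheno.columns[0])
    pheno.index = pheno.index.astype(str)
    missing = [c for c in (trait, *covariates) if c not in pheno.columns]
    if weight_col and weight_col not in pheno.columns:
        missing.append(weight_col)
    if missing:
        raise DataError(f"phenotype file lacks column(s): {', '.join(missing)}")

    geno_path = Path(geno_path)
    genos = (
        _read_vcf(geno_path)
        if geno_path.suffix.lower() == ".vcf" or str(geno_path).endswith(".vcf.gz")
        else _read_dosage_table(geno_path)
    )
    genos.index = genos.index.astype(str)

    shared = pheno.index.intersection(genos.index)
    if shared.empty:
        raise DataError("no overlapping sample ids between phenotype and genotype files")
    n_drop_join = len(pheno) - len(shared)
    if n_drop_join:
        logger.warning("dropped %d phenotype rows absent from genotypes", n_drop_join)
    pheno = pheno.loc[shared]
    genos = genos.loc[shared]

    use = [trait, *covariates] + ([weight_col] if weight_col else [])
    complete = pheno[use].notna().all(axis=1)
    if (~complete).sum():
        logger.warning("dropped %d incomplete-case rows", int((~complete).sum()))
    pheno = pheno.loc[complete]
    genos = genos.loc[pheno.index]

    cov = expand_categoricals(pheno[list(covariates)], tuple(categorical))
    table = CohortTable(
        sample_ids=pheno.index,
        trait=pheno[trait].to_numpy(dtype=float),
        covariates=cov,
        weights=pheno[weight_col].to_numpy(dtype=float) if weight_col else None,
    )
    return table, GenotypeMatrix(sample_ids=pheno.index, dosages=genos)


def conditional_pair_analysis(
    cohort: CohortTable,
    genos: GenotypeMatrix,
    index_snp: str,
    other_snp: str,
    maf_warn: float = MAF_WARN,
    r2_warn: float = R2_WARN,
    min_carriers: int = MIN_CARRIERS,
) -> PairwiseResult:
    """Adjusted conditional and interaction tests for one SNP pair.

    Complete-case per pair (samples missing either genotype are dropped).
    Degenerate fits are reported as flags on the row, never as exceptions.
    """
    g1 = genos.dosage(index_snp)
    g2 = genos.dosage(other_snp)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    n_used = int(ok.sum())
    if n_used < len(g1):
        logger.warning(
            "pair (%s, %s): dropped %d samples with missing genotypes",
            index_snp, other_snp, len(g1) - n_used,
        )
    flags: list[str] = []
    if n_used == 0:
        return PairwiseResult(index_snp, other_snp, np.nan, np.nan,
                              *[np.nan] * 6, 0, ["no_genotyped_samples"])

    y = cohort.trait[ok]
    cov = cohort.covariates.iloc[ok] if len(cohort.covariates.columns) else None
    w = cohort.weights[ok] if cohort.weights is not None else None

    maf_other = maf(g2[ok])
    try:
        r2 = ld_r2(g1[ok], g2[ok])
    except UndefinedLDError:
        r2 = np.nan
        flags.append("monomorphic")

    if maf_other < maf_warn:
        flags.append("rare_variant")
    carriers = int(np.sum(g2[ok] > 0))
    if 0 < carriers < min_carriers:
        if "rare_variant" not in flags:
            flags.append("rare_variant")
        flags.append(f"few_carriers({carriers})")
    if np.isfinite(r2) and r2 > r2_warn:
        flags.append("collinear")

    res = SignalIndependenceModel(
        y, g1[ok], g2[ok], covariates=cov, weights=w,
        snp_names=(index_snp, other_snp),
    ).fit()
    if res.alg1.failed:
        flags.append("alg1_failed")
    if res.alg2.failed:
        flags.append("alg2_failed")
    return PairwiseResult(
        index_snp=index_snp,
        other_snp=other_snp,
        maf_other=maf_other,
        r2=r2,
        alg1_beta=res.alg1.coef_target,
        alg1_se=res.alg1.se_target,
        alg1_p=res.alg1.p_target,
        alg2_beta=res.alg2.coef_target,
        alg2_se=res.alg2.se_target,
        alg2_p=res.alg2.p_target,
        n_used=n_used,
        flags=flags,
    )


_REPORT_COLS = [
    "index_snp", "other_snp", "maf_other", "r2",
    "alg1_beta", "alg1_se", "alg1_p",
    "alg2_beta", "alg2_se", "alg2_p",
    "n_used", "flags",
]


def pairs_frame(results: list) -> pd.DataFrame:
    if not results:
        raise InvalidParameterError("no pairwise results to report")
    rows = []
    for r in results:
        d = {c: getattr(r, c) for c in _REPORT_COLS[:-1]}
        d["flags"] = ";".join(r.flags) if r.flags else "."
        rows.append(d)
    return pd.DataFrame(rows, columns=_REPORT_COLS)


def report_pairs(results: list, path) -> pd.DataFrame:
    """Write the pairwise report as a tab-separated table (6 sig. digits)."""
    df = pairs_frame(results)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
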