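"""Synthetic cohort generator with LD-structured SNP pairs.

Emulates the statistical structure of a multi-cohort pharmacogenetic
analysis of a continuous trait (a bronchodilator-response-like outcome):
one common index SNP, companion SNPs at controlled pairwise LD with it —
including a near-duplicate at r^2 ~ 0.995 and a rare variant — plus
cohort/age/sex/BMI-category/ancestry covariates, per-subject weights and a
trait generated from a known linear model.  Every generating coefficient is
returned in a truth record so parameter-recovery tests are possible.

Genotypes are built at the haplotype level assuming Hardy-Weinberg
equilibrium: for allele frequencies p, q and a signed correlation r the
haplotype table uses D = r*sqrt(p(1-p)q(1-q)); two haplotypes are drawn
independently per subject and summed to a dosage.  The requested r must
satisfy the Lewontin feasibility bounds
``max(-pq, -(1-p)(1-q)) <= D <= min(p(1-q), q(1-p))``; an infeasible
(MAF, r^2) combination raises a `FeasibilityError` reporting the attainable
bound.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, GenotypeMatrix, expand_categoricals
from .exceptions import FeasibilityError, InvalidParameterError

__all__ = [
    "LDPairSpec",
    "SNPSpec",
    "CohortSpec",
    "haplotype_frequencies",
    "simulate_ld_pair",
    "simulate_cohort",
    "SyntheticCohort",
    "write_vcf",
]


@dataclass
class LDPairSpec:
    """One SNP pair: sample size, allele frequencies and target r^2."""

    n: int
    maf1: float
    maf2: float
    target_r2: float
    sign: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidParameterError("n must be >= 1")
        for m in (self.maf1, self.maf2):
            if not 0.0 < m <= 0.5:
                raise InvalidParameterError(f"MAF must lie in (0, 0.5], got {m}")
        if not 0.0 <= self.target_r2 <= 1.0:
            raise InvalidParameterError("target_r2 must lie in [0, 1]")
        if self.sign not in (-1, 1):
            raise InvalidParameterError("sign must be +1 or -1")


def haplotype_frequencies(
    maf1: float, maf2: float, target_r2: float, sign: int = 1
) -> np.ndarray:
    """2x2 haplotype table [[p00, p01], [p10, p11]] realising the target LD.

    Rows index the first SNP's allele, columns the second's; margins equal
    the requested allele frequencies exactly (construction-time check).
    """
    p, q = maf1, maf2
    denom = math.sqrt(p * (1 - p) * q * (1 - q))
    d = sign * math.sqrt(target_r2) * denom
    d_max = min(p * (1 - q), q * (1 - p))
    d_min = max(-p * q, -(1 - p) * (1 - q))
    if d > d_max + 1e-12 or d < d_min - 1e-12:
        r2_max = (d_max if sign > 0 else -d_min) / denom
        raise FeasibilityError(
            f"target r^2={target_r2:g} infeasible for MAFs ({p:g}, {q:g}); "
            f"max attainable r^2 at this sign is {r2_max**2:.4g}"
        )
    tab = np.array(
        [
            [(1 - p) * (1 - q) + d, (1 - p) * q - d],
            [p * (1 - q) - d, p * q + d],
        ]
    )
    tab = np.clip(tab, 0.0, None)
    tab /= tab.sum()
    assert np.allclose(tab.sum(axis=1), [1 - p, p], atol=1e-12)
    assert np.allclose(tab.sum(axis=0), [1 - q, q], atol=1e-12)
    return tab


def _conditional_alleles(a: np.ndarray, tab: np.ndarray, rng) -> np.ndarray:
    """Second-locus allele per haplotype, conditional on the first locus."""
    p0 = tab[0, 1] / tab[0].sum()  # P(b=1 | a=0)
    p1 = tab[1, 1] / tab[1].sum()  # P(b=1 | a=1)
    pb = np.where(a == 1, p1, p0)
    return (rng.random(a.shape) < pb).astype(np.int8)


def simulate_ld_pair(spec: LDPairSpec, rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw dosage vectors for one SNP pair at the specified LD.

    Two haplotypes per subject are drawn independently (HWE); dosage is the
    per-subject allele count, so the empirical dosage correlation converges
    to the haplotype-level r as n grows.
    """
    tab = haplotype_frequencies(spec.maf1, spec.maf2, spec.target_r2, spec.sign)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    a = (rng.random((spec.n, 2)) < spec.maf1).astype(np.int8)
    b = _conditional_alleles(a, tab, rng)
    return a.sum(axis=1).astype(np.int8), b.sum(axis=1).astype(np.int8)


@dataclass
class SNPSpec:
    """A companion SNP defined by its MAF and target r^2 with the index SNP."""

    name: str
    maf: float
    target_r2: float
    sign: int = 1


def _default_snps() -> tuple:
    return (
        SNPSpec("snpB", 0.32, 0.995),
        SNPSpec("snpC", 0.31, 0.891),
        SNPSpec("snpR", 0.001, 0.002),
    )


def _default_covariate_betas() -> dict:
    return {
        "age": -0.01,
        "sex": 0.10,
        "bmi_obese": -0.20,
        "bmi_overweight": -0.10,
        "cohort_CARE": 0.10,
        "cohort_LODO": -0.10,
        "ancestry": 0.05,
    }


@dataclass
class CohortSpec:
    """Full synthetic-cohort recipe; defaults mirror a three-cohort asthma
    study of 892 children (560/206/126 split) with a common index SNP at
    MAF 0.32, two highly correlated companions and one rare variant."""

    n: int = 892
    index_name: str = "snpA"
    index_maf: float = 0.32
    snps: tuple = field(default_factory=_default_snps)
    cohort_levels: tuple = ("CAMP", "CARE", "LODO")
    cohort_probs: tuple = (560 / 892, 206 / 892, 126 / 892)
    age_range: tuple = (5.0, 18.0)
    bmi_levels: tuple = ("normal", "overweight", "obese")
    bmi_probs: tuple = (0.60, 0.25, 0.15)
    beta0: float = 0.0
    snp_betas: dict = field(default_factory=lambda: {"snpA": -0.15})
    interaction_betas: dict = field(default_factory=dict)
    covariate_betas: dict = field(default_factory=_default_covariate_betas)
    sigma: float = 1.0
    weight_rule: str = "ones"  # "ones" | "random"
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.weight_rule not in ("ones", "random"):
            raise InvalidParameterError("weight_rule must be 'ones' or 'random'")
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be > 0")


@dataclass
class SyntheticCohort:
    """Generated cohort plus the generating truth; unpacks as a 3-tuple."""

    cohort: CohortTable
    genotypes: GenotypeMatrix
    truth: dict
    phenotypes_raw: pd.DataFrame

    def __iter__(self):
        return iter((self.cohort, self.genotypes, self.truth))

    def write(self, out_dir) -> dict:
        """Write VCF + covariate/trait table + truth record; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vcf = out / "genotypes.vcf"
        pheno = out / "phenotypes.tsv"
        truth = out / "truth.json"
        write_vcf(self.genotypes, vcf)
        self.phenotypes_raw.to_csv(pheno, sep="\t", index=True, index_label="sample_id")
        truth.write_text(json.dumps(self.truth, indent=2, default=str) + "\n")
        return {"vcf": vcf, "phenotypes": pheno, "truth": truth}


def _draw_snp_alleles(spec: CohortSpec, a: np.ndarray, snp: SNPSpec, rng) -> np.ndarray:
    tab = haplotype_frequencies(spec.index_maf, snp.maf, snp.target_r2, snp.sign)
    for attempt in range(spec.max_retries + 1):
        b = _conditional_alleles(a, tab, rng)
        dos = b.sum(axis=1)
        if dos.min() != dos.max():
            return dos.astype(np.int8)
    warnings.warn(
        f"SNP {snp.name} (MAF {snp.maf:g}) realised monomorphic after "
        f"{spec.max_retries} retries at n={spec.n}",
        stacklevel=2,
    )
    return dos.astype(np.int8)


def simulate_cohort(spec: CohortSpec, rng=None) -> SyntheticCohort:
    """Generate genotypes, covariates, weights and trait from a known model.

    Covariates: cohort ~ multinomial over the configured levels, age ~
    uniform over `age_range` (years), sex ~ Bernoulli(0.5), BMI category ~
    multinomial, ancestry score ~ N(0, 1).  Trait = linear predictor over
    SNP dosages, interactions and expanded covariate columns + N(0, sigma^2).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n

    # index SNP haplotypes anchor all pairwise LD targets
    a = (rng.random((n, 2)) < spec.index_maf).astype(np.int8)
    dosages = {spec.index_name: a.sum(axis=1).astype(np.int8)}
    for snp in spec.snps:
        dosages[snp.name] = _draw_snp_alleles(spec, a, snp, rng)
    geno_df = pd.DataFrame(dosages, index=pd.Index(
        [f"S{i:04d}" for i in range(n)], name="sample_id"))

    raw = pd.DataFrame(
        {
            "cohort": rng.choice(spec.cohort_levels, size=n, p=spec.cohort_probs),
            "age": rng.uniform(*spec.age_range, size=n).round(1),
            "sex": rng.integers(0, 2, size=n),
            "bmi": rng.choice(spec.bmi_levels, size=n, p=spec.bmi_probs),
            "ancestry": rng.normal(0.0, 1.0, size=n).round(4),
        },
        index=geno_df.index,
    )
    cov = expand_categoricals(raw, categorical=("cohort", "bmi"))

    eta = np.full(n, spec.beta0, dtype=float)
    for name, beta in spec.snp_betas.items():
        eta += beta * geno_df[name].to_numpy(dtype=float)
    for (s1, s2), beta in spec.interaction_betas.items():
        eta += beta * geno_df[s1].to_numpy(float) * geno_df[s2].to_numpy(float)
    for col, beta in spec.covariate_betas.items():
        if col in cov.columns:
            eta += beta * cov[col].to_numpy()
    y = eta + rng.normal(0.0, spec.sigma, size=n)

    if spec.weight_rule == "ones":
        w = np.ones(n)
    else:
        w = np.exp(rng.normal(0.0, 0.3, size=n))

    raw_out = raw.copy()
    raw_out.insert(0, "trait", np.round(y, 6))
    raw_out["weight"] = np.round(w, 6)

    cohort = CohortTable(
        sample_ids=geno_df.index, trait=y, covariates=cov, weights=w
    )
    genos = GenotypeMatrix(sample_ids=geno_df.index, dosages=geno_df)
    truth = {
        "beta0": spec.beta0,
        "snp_betas": dict(spec.snp_betas),
        "interaction_betas": {f"{a_}:{b_}": v for (a_, b_), v in
                              spec.interaction_betas.items()},
        "covariate_betas": dict(spec.covariate_betas),
        "sigma": spec.sigma,
        "design_columns": [spec.index_name, *[s.name for s in spec.snps],
                           *cov.columns],
        "spec": {k: v for k, v in asdict(spec).items() if k != "snps"},
        "snps": [asdict(s) for s in spec.snps],
    }
    return SyntheticCohort(cohort, genos, truth, raw_out)


def write_vcf(genos: GenotypeMatrix, path, chrom: str = "6",
              start_pos: int = 131570000) -> None:
    """Write dosages as a plain-text VCF with hard-call GT fields."""
    samples = [str(s) for s in genos.sample_ids]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for i, snp in enumerate(genos.snp_ids):
        dos = genos.dosage(snp)
        calls = [
            "./." if np.isnan(d) else gt_map[int(round(d))] for d in dos
        ]
        lines.append(
            f"{chrom}\t{start_pos + i}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t"
            + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")
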