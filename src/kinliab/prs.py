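"""Polygenic risk scoring and incremental variance explained.

Scores are weighted allele-count sums restricted to SNPs whose discovery
p-value falls at or below a threshold, after aligning the genotype allele
coding to the weight file's effect allele.  Predictive value is summarized
as incremental R^2: the variance explained by covariates plus score minus
that of the covariates alone (10 genotype principal components in the
standard analysis).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "WeightSet",
    "GenotypeMatrix",
    "ScoreProfile",
    "IncrementalR2Result",
    "DEFAULT_THRESHOLDS",
    "align_and_score",
    "score_profile",
    "incremental_r2",
    "threshold_sweep",
    "read_weight_file",
    "write_weight_file",
    "read_genotype_file",
    "write_genotype_file",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 1.00)

_VALID_ALLELES = {"A", "C", "G", "T"}
_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass(frozen=True)
class WeightSet:
    """GWAS summary-statistic weights: one row per SNP.

    Columns: ``snp_id, effect_allele, other_allele, beta, pvalue`` with
    betas on the log-odds scale of the discovery study.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "effect_allele", "other_allele", "beta", "pvalue"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"weight table lacks columns: {sorted(missing)}")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids in weight table")
        p = self.table["pvalue"]
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        alleles = set(self.table["effect_allele"]) | set(self.table["other_allele"])
        if not alleles <= _VALID_ALLELES:
            raise ValueError(f"invalid allele codes: {alleles - _VALID_ALLELES}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Individuals-by-SNPs dosage matrix with allele codes.

    ``dosages[i, j]`` counts copies of ``allele1[j]`` carried by individual
    *i* (0/1/2, ``NaN`` for missing).
    """

    dosages: np.ndarray
    snp_ids: list[str]
    allele1: list[str]
    allele2: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if not np.issubdtype(self.dosages.dtype, np.floating):
            self.dosages = self.dosages.astype(np.float32)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosage matrix shape inconsistent with SNP ids")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]


@dataclass(frozen=True)
class ScoreProfile:
    """Per-individual polygenic scores at each discovery p-value threshold."""

    scores: pd.DataFrame          # one column per threshold
    thresholds: tuple[float, ...]
    n_snps: dict[float, int]


@dataclass(frozen=True)
class IncrementalR2Result:
    r2_increment: float
    p_value: float
    n: int
    n_snps: int = 0

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r2_increment <= 1.0:
            raise ValueError("R^2 increment must lie in [0, 1]")


def align_and_score(genotypes: GenotypeMatrix, weights: WeightSet,
                    p_threshold: float = 1.0,
                    drop_ambiguous: bool = False) -> np.ndarray:
    """Per-individual weighted allele-count score at one p-value threshold.

    SNP inclusion is inclusive (``pvalue <= p_threshold``).  Genotype coding
    is aligned to the effect allele: when the weight file's effect/other
    alleles are swapped relative to the genotype coding the dosage is
    reflected (``2 - d``); SNPs whose alleles cannot be reconciled are
    dropped (counted in the log).  Missing dosages are imputed with the
    per-SNP mean (twice the sample allele frequency).
    """
    w = weights.table[weights.table["pvalue"] <= p_threshold]
    geno_idx = {s: j for j, s in enumerate(genotypes.snp_ids)}
    w = w[w["snp_id"].isin(geno_idx)]
    if len(w) == 0:
        raise ValueError(f"no SNPs shared with the weight file at "
                         f"p <= {p_threshold}")
    cols = np.array([geno_idx[s] for s in w["snp_id"]])
    g1 = np.array(genotypes.allele1, dtype=object)[cols]
    g2 = np.array(genotypes.allele2, dtype=object)[cols]
    ea = w["effect_allele"].to_numpy(object)
    oa = w["other_allele"].to_numpy(object)
    same = (ea == g1) & (oa == g2)
    flipped = (ea == g2) & (oa == g1)
    keep = same | flipped
    if drop_ambiguous:
        ambiguous = np.array(
            [frozenset({a, b}) in _AMBIGUOUS for a, b in zip(ea, oa)])
        keep &= ~ambiguous
    dropped = int((~keep).sum())
    if dropped:
        logger.info("align_and_score: dropped %d of %d SNPs "
                    "(allele mismatch or ambiguous)", dropped, len(w))
    if not keep.any():
        raise ValueError("no alignable SNPs at this threshold")
    D = genotypes.dosages[:, cols[keep]]
    if np.isnan(D).any():
        D = D.copy()
        col_mean = np.nanmean(D, axis=0)  # 2 x sample allele frequency
        nan_r, nan_c = np.where(np.isnan(D))
        D[nan_r, nan_c] = col_mean[nan_c]
    # flipped coding: beta * (2 - d) = 2 * beta - beta * d
    beta = w["beta"].to_numpy(float)[keep]
    flip = flipped[keep]
    signed = np.where(flip, -beta, beta).astype(D.dtype)
    return (D @ signed).astype(float) + 2.0 * float(beta[flip].sum())


def incremental_r2(outcome, score, covariates=None) -> IncrementalR2Result:
    """R^2 gain of adding the score to a covariate-only linear model.

    Returns the difference ``R^2(outcome ~ covariates + score) -
    R^2(outcome ~ covariates)`` together with the t-test p-value of the
    score coefficient in the full model.
    """
    y = np.asarray(outcome, float)
    s = np.asarray(score, float)
    n = len(y)
    if covariates is None:
        covariates = np.empty((n, 0))
    X_cov = np.column_stack([np.ones(n), np.asarray(covariates, float)])
    if n <= X_cov.shape[1] + 2:
        raise ValueError("too few observations for the covariate set")
    X_full = np.column_stack([X_cov, s])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("score is collinear with the covariates")
    fit_cov = sm.OLS(y, X_cov).fit()
    fit_full = sm.OLS(y, X_full).fit()
    inc = float(fit_full.rsquared - fit_cov.rsquared)
    p = float(fit_full.pvalues[-1])
    return IncrementalR2Result(r2_increment=min(max(inc, 0.0), 1.0),
                               p_value=p, n=n)


def score_profile(genotypes: GenotypeMatrix, weights: WeightSet,
                  thresholds=DEFAULT_THRESHOLDS,
                  drop_ambiguous: bool = False) -> ScoreProfile:
    """Polygenic scores of every individual at each p-value threshold."""
    thresholds = tuple(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    scores = {}
    n_snps = {}
    for pt in thresholds:
        scores[pt] = align_and_score(genotypes, weights, pt,
                                     drop_ambiguous=drop_ambiguous)
        n_snps[pt] = int((weights.table["pvalue"] <= pt).sum())
    return ScoreProfile(scores=pd.DataFrame(scores), thresholds=thresholds,
                        n_snps=n_snps)


def threshold_sweep(genotypes: GenotypeMatrix, weights: WeightSet,
                    outcome, covariates=None,
                    thresholds=DEFAULT_THRESHOLDS,
                    drop_ambiguous: bool = False) -> pd.DataFrame:
    """Incremental R^2 across discovery p-value thresholds.

    Returns one row per threshold: ``pT, n_snps, r2_increment, p_value``.
    """
    profile = score_profile(genotypes, weights, thresholds, drop_ambiguous)
    rows = []
    for pt in profile.thresholds:
        res = incremental_r2(outcome, profile.scores[pt], covariates)
        rows.append({"pT": pt, "n_snps": profile.n_snps[pt],
                     "r2_increment": res.r2_increment,
                     "p_value": res.p_value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------


def write_weight_file(weights: WeightSet, path) -> None:
    weights.table.to_csv(path, sep="\t", index=False,
                         columns=["snp_id", "effect_allele", "other_allele",
                                  "beta", "pvalue"])


def read_weight_file(path) -> WeightSet:
    return WeightSet(pd.read_csv(path, sep="\t"))


def write_genotype_file(genotypes: GenotypeMatrix, path) -> None:
    """Transposed PLINK-style text: one SNP per line, ``snp_id a1 a2`` then
    per-individual dosages of a1 (0/1/2, NA for missing)."""
    with open(path, "w") as fh:
        for j, snp in enumerate(genotypes.snp_ids):
            d = genotypes.dosages[:, j]
            vals = " ".join("NA" if math.isnan(v) else str(int(v)) for v in d)
            fh.write(f"{snp} {genotypes.allele1[j]} {genotypes.allele2[j]} "
                     f"{vals}\n")


def read_genotype_file(path) -> GenotypeMatrix:
    snp_ids, a1, a2, rows = [], [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            snp_ids.append(parts[0])
            a1.append(parts[1])
            a2.append(parts[2])
            rows.append([float("nan") if v == "NA" else float(v)
                         for v in parts[3:]])
    dosages = np.asarray(rows, float).T
    return GenotypeMatrix(dosages=dosages, snp_ids=snp_ids,
                          allele1=a1, allele2=a2)
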