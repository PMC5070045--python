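"""Descriptive familial aggregation: concordance summaries and odds ratios.

Two exposures are contrasted against deprived-neighborhood residence:

* an individual's own affection status (within-person odds ratio), and
* the affection status of a proband's sibling or co-twin (proband-to-
  relative odds ratio), which rises with relatedness when the overlap is
  genetically mediated.

Pairs in which both members are affected contribute both orientations
(double entry); logistic-regression variants therefore use cluster-robust
(by pair) standard errors.  Covariate-free tables fall back to the Woolf
log-odds interval, with a Haldane-Anscombe 0.5 correction when a cell is
empty.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable",
    "ORResult",
    "pair_concordance_summary",
    "proband_relative_or",
    "individual_or",
    "odds_ratio_from_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-outcome counts for one stratum."""

    counts: np.ndarray
    stratum: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, float)
        object.__setattr__(self, "counts", c)
        if c.shape != (2, 2) or np.any(c < 0):
            raise ValueError("counts must be a non-negative 2x2 matrix")


@dataclass(frozen=True)
class ORResult:
    or_point: float
    ci95: tuple[float, float]
    n: int
    method: str
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.or_point <= 0:
            raise ValueError("odds ratio must be positive")
        if not self.ci95[0] <= self.or_point <= self.ci95[1]:
            raise ValueError("interval must contain the point estimate")


def pair_concordance_summary(cohort, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-pair-type summary of affection and deprivation concordance.

    For every pair type: the percentage of pairs with at least one affected
    member (trait 1), and the proportion of pairs where at least one member
    ever lived in a deprived neighborhood (trait 2) - overall and split by
    pair affectedness - each with a binomial (Wilson) confidence interval.
    Empty strata are omitted with a warning.
    """
    df = getattr(cohort, "records", cohort)
    alpha = 1.0 - ci_level
    rows = []
    for pt, grp in df.groupby("pair_type"):
        if len(grp) == 0:  # pragma: no cover - groupby drops empty levels
            warnings.warn(f"empty stratum {pt!r} omitted", stacklevel=2)
            continue
        affected = (grp["trait1_m1"] | grp["trait1_m2"]).astype(bool)
        deprived = (grp["trait2_m1"] | grp["trait2_m2"]).astype(bool)

        def prop(mask_num, mask_den=None):
            den = len(grp) if mask_den is None else int(mask_den.sum())
            num = int(mask_num.sum())
            if den == 0:
                return (float("nan"), (float("nan"), float("nan")), 0)
            lo, hi = proportion_confint(num, den, alpha=alpha, method="wilson")
            return num / den, (float(lo), float(hi)), den

        p_aff, ci_aff, n_all = prop(affected)
        p_dep, ci_dep, _ = prop(deprived)
        p_dep_aff, ci_dep_aff, n_aff = prop(deprived & affected, affected)
        p_dep_un, ci_dep_un, n_un = prop(deprived & ~affected, ~affected)
        rows.append({
            "pair_type": pt, "n_pairs": n_all,
            "pct_affected": 100 * p_aff,
            "pct_affected_lo": 100 * ci_aff[0], "pct_affected_hi": 100 * ci_aff[1],
            "prop_deprived": p_dep,
            "prop_deprived_lo": ci_dep[0], "prop_deprived_hi": ci_dep[1],
            "prop_deprived_affected": p_dep_aff,
            "prop_deprived_affected_lo": ci_dep_aff[0],
            "prop_deprived_affected_hi": ci_dep_aff[1],
            "n_affected_pairs": n_aff,
            "prop_deprived_unaffected": p_dep_un,
            "prop_deprived_unaffected_lo": ci_dep_un[0],
            "prop_deprived_unaffected_hi": ci_dep_un[1],
        })
    return pd.DataFrame(rows)


def odds_ratio_from_table(table: ContingencyTable) -> ORResult:
    """Cross-product odds ratio with a Woolf interval on the log scale.

    ``counts[e, o]`` holds the number of observations with exposure *e* and
    outcome *o* (1 = exposed/outcome first row/column).  A zero cell
    triggers the Haldane-Anscombe correction (0.5 added to every cell),
    flagged in the result.
    """
    c = table.counts
    n = int(c.sum())
    corrected = bool(np.any(c == 0))
    if corrected:
        c = c + 0.5
    or_point = (c[0, 0] * c[1, 1]) / (c[0, 1] * c[1, 0])
    se = math.sqrt((1.0 / c).sum())
    z = norm.isf(0.025)
    ci = (or_point * math.exp(-z * se), or_point * math.exp(z * se))
    return ORResult(or_point=float(or_point), ci95=ci, n=n, method="Woolf",
                    corrected=corrected)


def _table_from_rows(exposure: np.ndarray, outcome: np.ndarray,
                     stratum: str) -> ContingencyTable:
    counts = np.array([
        [np.sum((exposure == 1) & (outcome == 1)),
         np.sum((exposure == 1) & (outcome == 0))],
        [np.sum((exposure == 0) & (outcome == 1)),
         np.sum((exposure == 0) & (outcome == 0))],
    ], float)
    return ContingencyTable(counts=counts, stratum=stratum)


def _logistic_or(exposure, outcome, covariates, groups) -> ORResult:
    X = sm.add_constant(np.column_stack([exposure, covariates]))
    model = sm.GLM(outcome, X, family=sm.families.Binomial())
    res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    beta = float(res.params[1])
    se = float(res.bse[1])
    z = norm.isf(0.025)
    return ORResult(or_point=math.exp(beta),
                    ci95=(math.exp(beta - z * se), math.exp(beta + z * se)),
                    n=len(outcome), method="logistic")


def _double_entry(df: pd.DataFrame):
    """Proband-to-relative rows: each pair contributes both orientations."""
    exp = np.concatenate([df["trait1_m1"].to_numpy(int),
                          df["trait1_m2"].to_numpy(int)])
    out = np.concatenate([df["trait2_m2"].to_numpy(int),
                          df["trait2_m1"].to_numpy(int)])
    groups = np.concatenate([df["pair_id"].to_numpy(),
                             df["pair_id"].to_numpy()])
    return exp, out, groups


def proband_relative_or(cohort, relation: str,
                        covariates: list[str] | None = None) -> ORResult:
    """Odds ratio for deprived residence of the relative of an affected
    proband, within one pair type.

    With covariates: cluster-robust logistic regression on double-entered
    rows.  Without: Woolf interval on the double-entered 2x2 table.
    """
    df = getattr(cohort, "records", cohort)
    df = df[df["pair_type"] == relation]
    exp, out, groups = _double_entry(df)
    if exp.sum() == 0 or (1 - exp).sum() == 0:
        raise ValueError(f"need exposed and unexposed probands in {relation!r}")
    if covariates:
        cov = np.concatenate([df[[f"{c}_m2" for c in covariates]].to_numpy(float),
                              df[[f"{c}_m1" for c in covariates]].to_numpy(float)])
        return _logistic_or(exp, out, cov, groups)
    return odds_ratio_from_table(_table_from_rows(exp, out, relation))


def individual_or(cohort, covariates: list[str] | None = None,
                  pair_type: str | None = None) -> ORResult:
    """Odds ratio for deprived residence given the person's own affection
    status (both pair members contribute one row each)."""
    df = getattr(cohort, "records", cohort)
    if pair_type is not None:
        df = df[df["pair_type"] == pair_type]
    exp = np.concatenate([df["trait1_m1"].to_numpy(int),
                          df["trait1_m2"].to_numpy(int)])
    out = np.concatenate([df["trait2_m1"].to_numpy(int),
                          df["trait2_m2"].to_numpy(int)])
    groups = np.concatenate([df["pair_id"].to_numpy(),
                             df["pair_id"].to_numpy()])
    if exp.sum() == 0 or (1 - exp).sum() == 0:
        raise ValueError("need both exposed and unexposed individuals")
    if covariates:
        cov = np.concatenate([df[[f"{c}_m1" for c in covariates]].to_numpy(float),
                              df[[f"{c}_m2" for c in covariates]].to_numpy(float)])
        return _logistic_or(exp, out, cov, groups)
    return odds_ratio_from_table(_table_from_rows(exp, out, pair_type or "all"))
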