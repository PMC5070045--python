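"""Synthetic cohorts with known generating parameters.

Generates the three kinds of data the estimation modules consume:

* pair-level phenotype cohorts (sibling or twin designs) drawn from a
  multivariate-normal liability model with a specified A/C/E structure and
  prevalence-matched thresholds;
* continuous neighborhood-deprivation scores dichotomized at an empirical
  percentile (95th for registry-style cohorts, 75th for small twin samples);
* genotype/weight/outcome cohorts for polygenic-score analysis, with
  independent binomial allele counts and true effects scaled to a target
  variance explained.

All randomness flows from a single root seed through deterministically
spawned child streams, so identical seed + configuration reproduces a
byte-identical cohort.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cholesky_bivariate import CholeskyPaths, implied_pair_covariance
from .liability_model import DEFAULT_RELATEDNESS, RelatednessMap
from .prs import GenotypeMatrix, WeightSet

__all__ = [
    "GeneratingModel",
    "SimulatedCohort",
    "PrsCohort",
    "threshold_from_prevalence",
    "simulate_univariate_pairs",
    "simulate_bivariate_pairs",
    "deprivation_binarize",
    "select_pairs",
    "simulate_prs_cohort",
    "write_pair_table",
    "read_pair_table",
]

PAIR_COLUMNS = ["pair_id", "pair_type", "trait1_m1", "trait1_m2",
                "trait2_m1", "trait2_m2", "sex_m1", "sex_m2",
                "birthyear_m1", "birthyear_m2"]


def threshold_from_prevalence(K: float) -> float:
    """Liability threshold whose standard-normal upper-tail mass equals *K*."""
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {K!r}")
    return float(norm.isf(K))


@dataclass(frozen=True)
class GeneratingModel:
    """True parameters of a simulated liability model.

    Univariate cohorts use ``a2/c2/e2`` and the trait-1 prevalences;
    bivariate cohorts additionally need Cholesky ``paths`` and trait-2
    prevalences.  ``covariate_effects`` holds probit slopes (per covariate
    name) that shift individual thresholds when enabled; the default
    simulations are covariate-free.
    """

    a2: float
    c2: float
    e2: float
    prevalence_by_stratum: dict[str, float]
    prevalence2_by_stratum: dict[str, float] | None = None
    paths: CholeskyPaths | None = None
    covariate_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-10:
            raise ValueError("a2 + c2 + e2 must equal 1")
        if min(self.a2, self.c2, self.e2) < 0:
            raise ValueError("variance proportions must be non-negative")
        for d in (self.prevalence_by_stratum, self.prevalence2_by_stratum):
            if d is None:
                continue
            for k, v in d.items():
                if not 0.0 < v < 1.0:
                    raise ValueError(f"prevalence for {k!r} must be in (0, 1)")

    @classmethod
    def univariate(cls, a2: float, c2: float, prevalence: float,
                   pair_types=("MZ", "DZ", "FS", "MHS", "PHS")) -> "GeneratingModel":
        prev = {pt: prevalence for pt in pair_types}
        return cls(a2=a2, c2=c2, e2=1.0 - a2 - c2, prevalence_by_stratum=prev)

    @classmethod
    def bivariate(cls, paths: CholeskyPaths, prevalence1: float,
                  prevalence2: float,
                  pair_types=("MZ", "DZ", "FS", "MHS", "PHS")) -> "GeneratingModel":
        vc1 = paths.standardized().marginal_components(1)
        return cls(a2=vc1.a2, c2=vc1.c2, e2=vc1.e2,
                   prevalence_by_stratum={pt: prevalence1 for pt in pair_types},
                   prevalence2_by_stratum={pt: prevalence2 for pt in pair_types},
                   paths=paths.standardized())


@dataclass
class SimulatedCohort:
    """A simulated pair cohort plus its provenance."""

    records: pd.DataFrame
    seed: int
    generating_model: GeneratingModel
    counts_by_pair_type: dict[str, int]

    def __post_init__(self) -> None:
        total = sum(self.counts_by_pair_type.values())
        if total != len(self.records):
            raise ValueError("pair-type counts do not sum to record count")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _covariates(rng: np.random.Generator, n: int):
    sex = rng.integers(1, 3, size=(n, 2))
    by = rng.integers(1951, 1975, size=(n, 2))
    return sex, by


def covariate_design(sex: np.ndarray, birthyear: np.ndarray) -> dict[str, np.ndarray]:
    """Centered covariate codings used for probit threshold shifts.

    Sex (1/2) is centered at 1.5; birth year is centered and scaled to unit
    spread over the cohort's span so slopes are comparable across covariates.
    """
    return {"sex": np.asarray(sex, float) - 1.5,
            "birthyear": (np.asarray(birthyear, float) - 1962.5) / 6.9}


def _threshold_shift(effects: dict[str, float], sex, by) -> np.ndarray:
    design = covariate_design(sex, by)
    shift = np.zeros(np.shape(sex), float)
    for name, beta in effects.items():
        if name not in design:
            raise ValueError(f"unknown covariate {name!r}; "
                             f"known: {sorted(design)}")
        shift = shift + beta * design[name]
    return shift


def _pair_frame(blocks: list[pd.DataFrame]) -> pd.DataFrame:
    df = pd.concat(blocks, ignore_index=True)
    df["pair_id"] = np.arange(len(df))
    return df[PAIR_COLUMNS]


def simulate_univariate_pairs(model: GeneratingModel,
                              relmap: RelatednessMap = DEFAULT_RELATEDNESS,
                              n_by_pair_type: dict[str, int] | None = None,
                              seed: int = 0) -> SimulatedCohort:
    """Draw pair liabilities from the implied bivariate normal and dichotomize.

    For pair type *s* the two liabilities are standard normal with
    correlation ``r_A(s) a2 + r_C(s) c2``; trait 1 is the indicator of
    exceeding the prevalence-matched threshold of that stratum.  Trait 2 is
    filled with zeros (use :func:`simulate_bivariate_pairs` for two traits).
    """
    if n_by_pair_type is None:
        raise ValueError("n_by_pair_type is required")
    pair_types = [pt for pt in n_by_pair_type if n_by_pair_type[pt] > 0]
    rngs = _child_rngs(seed, len(pair_types))
    blocks = []
    for pt, rng in zip(pair_types, rngs):
        n = int(n_by_pair_type[pt])
        r_a, r_c = relmap.pair(pt)  # raises for unknown pair type
        if pt not in model.prevalence_by_stratum:
            raise ValueError(f"no prevalence configured for pair type {pt!r}")
        r = r_a * model.a2 + r_c * model.c2
        t = threshold_from_prevalence(model.prevalence_by_stratum[pt])
        z = rng.standard_normal((n, 2))
        l1 = z[:, 0]
        l2 = r * z[:, 0] + math.sqrt(1.0 - r * r) * z[:, 1]
        sex, by = _covariates(rng, n)
        tt = t + _threshold_shift(model.covariate_effects, sex, by) \
            if model.covariate_effects else np.full((n, 2), t)
        blocks.append(pd.DataFrame({
            "pair_id": 0, "pair_type": pt,
            "trait1_m1": (l1 > tt[:, 0]).astype(int),
            "trait1_m2": (l2 > tt[:, 1]).astype(int),
            "trait2_m1": 0, "trait2_m2": 0,
            "sex_m1": sex[:, 0], "sex_m2": sex[:, 1],
            "birthyear_m1": by[:, 0], "birthyear_m2": by[:, 1],
        }))
    df = _pair_frame(blocks)
    return SimulatedCohort(records=df, seed=seed, generating_model=model,
                           counts_by_pair_type={pt: int(n_by_pair_type[pt])
                                                for pt in pair_types})


def simulate_bivariate_pairs(model: GeneratingModel,
                             relmap: RelatednessMap = DEFAULT_RELATEDNESS,
                             n_by_pair_type: dict[str, int] | None = None,
                             seed: int = 0) -> SimulatedCohort:
    """Draw 4-dimensional pair liabilities (two traits x two members) from the
    Cholesky-implied covariance and dichotomize each coordinate."""
    if n_by_pair_type is None:
        raise ValueError("n_by_pair_type is required")
    if model.paths is None or model.prevalence2_by_stratum is None:
        raise ValueError("bivariate simulation needs paths and trait-2 prevalences")
    pair_types = [pt for pt in n_by_pair_type if n_by_pair_type[pt] > 0]
    rngs = _child_rngs(seed, len(pair_types))
    blocks = []
    for pt, rng in zip(pair_types, rngs):
        n = int(n_by_pair_type[pt])
        sigma = implied_pair_covariance(model.paths, pt, relmap)
        w, V = np.linalg.eigh(sigma)
        if w.min() < -1e-8:
            raise ValueError(f"implied covariance for {pt!r} is not PSD")
        L = V * np.sqrt(np.clip(w, 0.0, None))
        liab = rng.standard_normal((n, 4)) @ L.T
        t1 = threshold_from_prevalence(model.prevalence_by_stratum[pt])
        t2 = threshold_from_prevalence(model.prevalence2_by_stratum[pt])
        sex, by = _covariates(rng, n)
        blocks.append(pd.DataFrame({
            "pair_id": 0, "pair_type": pt,
            "trait1_m1": (liab[:, 0] > t1).astype(int),
            "trait1_m2": (liab[:, 2] > t1).astype(int),
            "trait2_m1": (liab[:, 1] > t2).astype(int),
            "trait2_m2": (liab[:, 3] > t2).astype(int),
            "sex_m1": sex[:, 0], "sex_m2": sex[:, 1],
            "birthyear_m1": by[:, 0], "birthyear_m2": by[:, 1],
        }))
    df = _pair_frame(blocks)
    return SimulatedCohort(records=df, seed=seed, generating_model=model,
                           counts_by_pair_type={pt: int(n_by_pair_type[pt])
                                                for pt in pair_types})


def deprivation_binarize(scores, percentile: float = 0.95) -> np.ndarray:
    """Flag scores strictly above the empirical percentile.

    The cutoff is the lower empirical order statistic (``numpy`` method
    ``"lower"``), and ties at the cutoff are never flagged, so with heavy
    ties the flagged proportion can fall below ``1 - percentile``.
    """
    scores = np.asarray(scores, float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    cutoff = np.quantile(scores, percentile, method="lower")
    return (scores > cutoff).astype(int)


def select_pairs(family_table: pd.DataFrame) -> pd.DataFrame:
    """Select one sibling pair per family: the oldest two members born
    within five years of each other.

    Expects columns ``person_id, family_id, birth_year, mother_id,
    father_id``.  Pairs are classified as full (both parents shared),
    maternal-half or paternal-half siblings; a pair sharing neither parent
    (or with missing parent identifiers) raises ``ValueError``.
    """
    required = {"person_id", "family_id", "birth_year", "mother_id", "father_id"}
    missing = required - set(family_table.columns)
    if missing:
        raise ValueError(f"family table lacks columns: {sorted(missing)}")
    rows = []
    for fam, grp in family_table.groupby("family_id"):
        if len(grp) < 2:
            continue
        grp = grp.sort_values(["birth_year", "person_id"]).reset_index(drop=True)
        chosen = None
        for i, j in itertools.combinations(range(len(grp)), 2):
            if abs(grp.loc[j, "birth_year"] - grp.loc[i, "birth_year"]) <= 5:
                chosen = (i, j)
                break
        if chosen is None:
            continue
        m1, m2 = grp.loc[chosen[0]], grp.loc[chosen[1]]
        if pd.isna(m1["mother_id"]) or pd.isna(m1["father_id"]) \
                or pd.isna(m2["mother_id"]) or pd.isna(m2["father_id"]):
            raise ValueError(f"family {fam!r}: missing parent identifiers")
        same_mother = m1["mother_id"] == m2["mother_id"]
        same_father = m1["father_id"] == m2["father_id"]
        if same_mother and same_father:
            pt = "FS"
        elif same_mother:
            pt = "MHS"
        elif same_father:
            pt = "PHS"
        else:
            raise ValueError(f"family {fam!r}: pair shares no parent; "
                             "inconsistent parentage data")
        rows.append({"family_id": fam, "pair_type": pt,
                     "person_id_m1": m1["person_id"],
                     "person_id_m2": m2["person_id"],
                     "birth_year_m1": int(m1["birth_year"]),
                     "birth_year_m2": int(m2["birth_year"])})
    return pd.DataFrame(rows, columns=["family_id", "pair_type",
                                       "person_id_m1", "person_id_m2",
                                       "birth_year_m1", "birth_year_m2"])


@dataclass
class PrsCohort:
    """Genotypes, discovery weights, outcome and PC covariates, with truth."""

    genotypes: GenotypeMatrix
    weights: WeightSet
    outcome: np.ndarray
    pcs: np.ndarray
    true_r2: float
    seed: int


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def simulate_prs_cohort(n: int, m: int, maf_range=(0.05, 0.5),
                        target_r2: float = 0.0015, n_pcs: int = 10,
                        pc_r2: float = 0.02, seed: int = 0) -> PrsCohort:
    """Simulate a genotyped target cohort and a discovery weight file.

    Genotypes are independent ``Binomial(2, p)`` allele counts (no linkage
    disequilibrium, mirroring a pruned discovery panel).  Per-SNP effects
    are scaled so the true aggregate score explains ``target_r2`` of the
    continuous outcome's variance in expectation; ``n_pcs`` standard-normal
    covariates jointly explain ``pc_r2``.  Discovery p-values are uniform
    and independent of the effects, with the smallest forced below 0.01 so
    every conventional threshold selects a non-empty SNP set.
    """
    if not 0.0 <= target_r2 < 1.0:
        raise ValueError("target_r2 must lie in [0, 1)")
    if target_r2 + pc_r2 >= 1.0:
        raise ValueError("score and covariate variance shares exceed 1")
    rng_g, rng_b, rng_p, rng_y = _child_rngs(seed, 4)
    mafs = rng_g.uniform(*maf_range, size=m)
    # Binomial(2, p) as the sum of two Bernoulli draws, in float32: the
    # dosage matrix is by far the largest object in the pipeline
    mafs32 = mafs.astype(np.float32)
    dosages = ((rng_g.random((n, m), dtype=np.float32) < mafs32).astype(np.float32)
               + (rng_g.random((n, m), dtype=np.float32) < mafs32))
    betas = rng_b.standard_normal(m)
    var_raw = float(np.sum(betas ** 2 * 2 * mafs * (1 - mafs)))
    if target_r2 > 0:
        betas *= math.sqrt(target_r2 / var_raw)
    else:
        betas[:] = 0.0
    pvals = rng_b.uniform(size=m)
    if pvals.min() > 0.005:
        pvals[np.argmin(pvals)] = 0.005
    alleles = [
        _ALLELE_PAIRS[k] for k in rng_b.integers(0, len(_ALLELE_PAIRS), size=m)
    ]
    snp_ids = [f"snp{i:06d}" for i in range(m)]
    weights = WeightSet(pd.DataFrame({
        "snp_id": snp_ids,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "beta": betas,
        "pvalue": pvals,
    }))
    genotypes = GenotypeMatrix(
        dosages=dosages, snp_ids=list(snp_ids),
        allele1=[a for a, _ in alleles], allele2=[b for _, b in alleles],
    )
    score = dosages @ betas
    score -= score.mean()
    pcs = rng_p.standard_normal((n, n_pcs))
    gamma = (math.sqrt(pc_r2 / n_pcs) * np.ones(n_pcs) if n_pcs > 0
             else np.zeros(0))
    resid_sd = math.sqrt(max(1.0 - target_r2 - pc_r2, 0.0))
    outcome = score + pcs @ gamma + rng_y.standard_normal(n) * resid_sd
    return PrsCohort(genotypes=genotypes, weights=weights, outcome=outcome,
                     pcs=pcs, true_r2=target_r2, seed=seed)


def write_pair_table(cohort, path) -> None:
    """Write a pair table as tab-separated text with the canonical header."""
    df = getattr(cohort, "records", cohort)
    df.to_csv(path, sep="\t", index=False, columns=PAIR_COLUMNS)


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pair table lacks columns: {sorted(missing)}")
    return df
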