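"""Bivariate Cholesky liability-threshold model for two binary traits.

The two liabilities of one person are modelled with triangular A/C/E path
matrices (the Cholesky parameterization), which guarantees positive
semi-definite component covariance matrices::

    A = a a',  C = c c',  E = e e',   a, c, e lower-triangular 2x2

After standardization the within-person covariance A + C + E has unit
diagonal, so its off-diagonal entry is the latent (tetrachoric) correlation
between the traits and decomposes additively as r = A12 + C12 + E12.  Pair
resemblance enters through the cross-member block r_A * A + r_C * C with
pair-type coefficients from a :class:`~kinliab.liability_model.RelatednessMap`.

Fitting maximizes the 16-cell multinomial likelihood of the four
dichotomized liabilities per pair, with per-stratum thresholds for each
trait.  The 4-D normal rectangle probabilities use a deterministic
quasi-Monte-Carlo rule with a fixed internal seed.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from ._mvnorm import mvn_rectangle_masses
from ._numdiff import central_hessian
from .liability_model import (
    DEFAULT_RELATEDNESS,
    RelatednessMap,
    VarianceComponents,
    _canonical_strata,
    delta_method_ci,
    fit_univariate,
    tetrachoric,
)

__all__ = [
    "CholeskyPaths",
    "BivariateFit",
    "CorrelationDecomposition",
    "implied_pair_covariance",
    "orthant_probability_4d",
    "all_orthant_probabilities",
    "tabulate_pairs_bivariate",
    "loglik_bivariate",
    "fit_bivariate",
    "decompose_correlation",
]


@dataclass(frozen=True)
class CholeskyPaths:
    """Lower-triangular 2x2 path matrices for the A, C and E factors."""

    a: np.ndarray
    c: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        for name in ("a", "c", "e"):
            m = np.asarray(getattr(self, name), float)
            object.__setattr__(self, name, m)
            if m.shape != (2, 2) or abs(m[0, 1]) > 1e-12:
                raise ValueError(f"path matrix {name} must be 2x2 lower-triangular")

    @property
    def A(self) -> np.ndarray:
        return self.a @ self.a.T

    @property
    def C(self) -> np.ndarray:
        return self.c @ self.c.T

    @property
    def E(self) -> np.ndarray:
        return self.e @ self.e.T

    def within_person(self) -> np.ndarray:
        return self.A + self.C + self.E

    def standardized(self) -> "CholeskyPaths":
        """Rescale paths so each trait's total liability variance is 1."""
        d = np.sqrt(np.diag(self.within_person()))
        D = np.diag(1.0 / d)
        return CholeskyPaths(D @ self.a, D @ self.c, D @ self.e)

    def marginal_components(self, trait: int) -> VarianceComponents:
        """ACE proportions of one trait implied by the (standardized) paths."""
        i = trait - 1
        W = self.within_person()
        return VarianceComponents(self.A[i, i] / W[i, i],
                                  self.C[i, i] / W[i, i],
                                  self.E[i, i] / W[i, i])

    @classmethod
    def from_variance_components(
        cls, a2_1: float, c2_1: float, a2_2: float, c2_2: float,
        r_g: float = 0.0, r_c: float = 0.0, r_e: float = 0.0,
    ) -> "CholeskyPaths":
        """Build standardized paths from marginal ACE proportions and
        factor-specific cross-trait correlations (r_g genetic, r_c shared
        environment, r_e unique environment)."""
        e2_1 = 1.0 - a2_1 - c2_1
        e2_2 = 1.0 - a2_2 - c2_2
        if min(e2_1, e2_2) < -1e-10:
            raise ValueError("marginal components exceed total variance")
        mats = []
        for v1, v2, rho in ((a2_1, a2_2, r_g), (c2_1, c2_2, r_c),
                            (e2_1, e2_2, r_e)):
            x11 = math.sqrt(max(v1, 0.0))
            cov = rho * math.sqrt(max(v1, 0.0) * max(v2, 0.0))
            x21 = cov / x11 if x11 > 0 else 0.0
            if x11 == 0.0 and cov != 0.0:
                raise ValueError("cross covariance through a zero-variance factor")
            rem = v2 - x21 * x21
            if rem < -1e-10:
                raise ValueError("factor correlation incompatible with variances")
            mats.append(np.array([[x11, 0.0], [x21, math.sqrt(max(rem, 0.0))]]))
        return cls(*mats)


def implied_pair_covariance(paths: CholeskyPaths, pair_type: str,
                            relmap: RelatednessMap = DEFAULT_RELATEDNESS,
                            ) -> np.ndarray:
    """4x4 liability correlation matrix of a pair.

    Variable order: (trait1 member1, trait2 member1, trait1 member2,
    trait2 member2).  Within-person blocks are A + C + E; cross-member
    blocks are r_A A + r_C C.  Raises ``ValueError`` (naming the pair type)
    if the assembled matrix is not positive semi-definite.
    """
    r_a, r_c = relmap.pair(pair_type)
    W = paths.within_person()
    X = r_a * paths.A + r_c * paths.C
    sigma = np.block([[W, X], [X.T, W]])
    if np.linalg.eigvalsh(sigma).min() < -1e-8:
        raise ValueError(f"implied pair covariance for {pair_type!r} is not "
                         "positive semi-definite")
    return sigma


# ---------------------------------------------------------------------------
# orthant probabilities
# ---------------------------------------------------------------------------

_PATTERNS = np.array([[(idx >> (3 - k)) & 1 for k in range(4)]
                      for idx in range(16)], bool)


def _limits(thresholds: np.ndarray, patterns: np.ndarray):
    lower = np.where(patterns, thresholds[None, :], -np.inf)
    upper = np.where(patterns, np.inf, thresholds[None, :])
    return lower, upper


def orthant_probability_4d(sigma: np.ndarray, thresholds, pattern,
                           tol: float = 1e-6) -> float:
    """Probability that each of four jointly normal liabilities is above
    (pattern entry truthy) or below its threshold.

    Adaptive: the quasi-Monte-Carlo point budget doubles until the internal
    error estimate falls below ``tol``.
    """
    sigma = np.asarray(sigma, float)
    thresholds = np.asarray(thresholds, float)
    pat = np.asarray(pattern, bool).reshape(1, 4)
    if np.linalg.eigvalsh(sigma).min() < -1e-8:
        raise ValueError("sigma is not positive semi-definite")
    lower, upper = _limits(thresholds, pat)
    n = 1024
    while True:
        val, err = mvn_rectangle_masses(sigma, lower, upper, n=n, nshift=8,
                                        return_error=True)
        if err[0] < tol or n >= 2 ** 16:
            return float(val[0])
        n *= 2


def all_orthant_probabilities(sigma: np.ndarray, thresholds,
                              n: int = 1024, nshift: int = 8) -> np.ndarray:
    """All 16 dichotomization-pattern probabilities, index ``b1 b2 b3 b4``
    read as a binary number with 1 = above threshold."""
    thresholds = np.asarray(thresholds, float)
    lower, upper = _limits(thresholds, _PATTERNS)
    return mvn_rectangle_masses(np.asarray(sigma, float), lower, upper,
                                n=n, nshift=nshift)


def tabulate_pairs_bivariate(pairs: pd.DataFrame) -> dict[str, np.ndarray]:
    """Aggregate a two-trait pair table into per-stratum 16-cell counts.

    Cell index packs (trait1_m1, trait2_m1, trait1_m2, trait2_m2) as bits,
    most significant first, 1 meaning above threshold (affected/deprived).
    """
    bits = (pairs["trait1_m1"].to_numpy(int) * 8
            + pairs["trait2_m1"].to_numpy(int) * 4
            + pairs["trait1_m2"].to_numpy(int) * 2
            + pairs["trait2_m2"].to_numpy(int))
    out = {}
    for pt, idx in pairs.groupby("pair_type").indices.items():
        out[str(pt)] = np.bincount(bits[idx], minlength=16).astype(float)
    return out


# ---------------------------------------------------------------------------
# internal parameterization
# ---------------------------------------------------------------------------
# Trait 1 uses the univariate squared-path scheme (z_a1, z_c1).  The second
# Cholesky rows (a21, a22, c21, c22, e21, e22) are parameterized by five raw
# values with the raw e22 entry pinned to 1 and the whole row normalized to
# unit length, which enforces the unit-variance constraint exactly while
# keeping the map smooth and locally one-to-one.  Cross paths keep their
# sign; the sign of diagonal entries is irrelevant (only squares enter).

_N_STRUCT = 7


def _paths_from_internal(x: np.ndarray) -> CholeskyPaths:
    z_a1, z_c1 = x[0], x[1]
    d1 = math.sqrt(1.0 + z_a1 * z_a1 + z_c1 * z_c1)
    a11, c11, e11 = abs(z_a1) / d1, abs(z_c1) / d1, 1.0 / d1
    u = x[2:7]
    s = math.sqrt(1.0 + float(u @ u))
    a21, a22 = u[0] / s, abs(u[1]) / s
    c21, c22 = u[2] / s, abs(u[3]) / s
    e21, e22 = u[4] / s, 1.0 / s
    return CholeskyPaths(
        a=np.array([[a11, 0.0], [a21, a22]]),
        c=np.array([[c11, 0.0], [c21, c22]]),
        e=np.array([[e11, 0.0], [e21, e22]]),
    )


def _internal_from_paths(paths: CholeskyPaths) -> np.ndarray:
    p = paths.standardized()
    e11 = max(p.e[0, 0], 1e-3)
    e22 = max(p.e[1, 1], 1e-3)
    return np.array([
        p.a[0, 0] / e11, p.c[0, 0] / e11,
        p.a[1, 0] / e22, p.a[1, 1] / e22,
        p.c[1, 0] / e22, p.c[1, 1] / e22,
        p.e[1, 0] / e22,
    ])


def loglik_bivariate(params: np.ndarray, cell_counts: dict[str, np.ndarray],
                     relmap: RelatednessMap = DEFAULT_RELATEDNESS,
                     qmc_points: int = 512, qmc_shifts: int = 4) -> float:
    """16-cell multinomial log-likelihood of a two-trait pair dataset.

    ``params`` is ``[structural (7), t1 per stratum, t2 per stratum]`` with
    strata in canonical order.
    """
    params = np.asarray(params, float)
    strata = _canonical_strata(cell_counts)
    S = len(strata)
    if len(params) != _N_STRUCT + 2 * S:
        raise ValueError("parameter vector length does not match strata")
    paths = _paths_from_internal(params)
    sig_blocks, low_blocks, up_blocks, cnt_blocks = [], [], [], []
    for j, s in enumerate(strata):
        counts = np.asarray(cell_counts[s], float)
        if counts.sum() == 0:
            continue
        t1 = params[_N_STRUCT + j]
        t2 = params[_N_STRUCT + S + j]
        sigma = implied_pair_covariance(paths, s, relmap)
        lower, upper = _limits(np.array([t1, t2, t1, t2]), _PATTERNS)
        sig_blocks.append(np.broadcast_to(sigma, (16, 4, 4)))
        low_blocks.append(lower)
        up_blocks.append(upper)
        cnt_blocks.append(counts)
    p = mvn_rectangle_masses(np.concatenate(sig_blocks),
                             np.concatenate(low_blocks),
                             np.concatenate(up_blocks),
                             n=qmc_points, nshift=qmc_shifts)
    cnt = np.concatenate(cnt_blocks)
    pos = cnt > 0
    if np.any(p[pos] <= 0.0):
        return -np.inf
    return float(np.sum(cnt[pos] * np.log(p[pos])))


@dataclass
class BivariateFit:
    paths: CholeskyPaths
    thresholds: dict[str, tuple[float, float]]
    loglik: float
    params: np.ndarray
    vcov: np.ndarray | None
    strata: tuple[str, ...]
    relmap: RelatednessMap
    convergence: dict
    n_pairs: int = 0


def _marginal_counts(cell_counts: dict[str, np.ndarray], trait: int):
    """Collapse 16-cell bivariate counts to one trait's 4-cell counts."""
    out = {}
    for s, counts in cell_counts.items():
        four = np.zeros(4)
        for idx in range(16):
            bits = [(idx >> k) & 1 for k in (3, 2, 1, 0)]
            y1, y2 = (bits[0], bits[2]) if trait == 1 else (bits[1], bits[3])
            four[(1 - y1) * 2 + (1 - y2)] += counts[idx]
        out[s] = four
    return out


def _within_person_table(cell_counts: dict[str, np.ndarray]) -> np.ndarray:
    """Pooled 2x2 (trait1 x trait2) person-level table, both members."""
    tbl = np.zeros((2, 2))
    for counts in cell_counts.values():
        for idx in range(16):
            b = [(idx >> k) & 1 for k in (3, 2, 1, 0)]
            tbl[1 - b[0], 1 - b[1]] += counts[idx]
            tbl[1 - b[2], 1 - b[3]] += counts[idx]
    return tbl


def fit_bivariate(data, relmap: RelatednessMap = DEFAULT_RELATEDNESS,
                  qmc_points: int = 512, qmc_shifts: int = 4,
                  compute_ci: bool = True,
                  start: np.ndarray | None = None) -> BivariateFit:
    """Maximum-likelihood bivariate Cholesky fit to two-trait pair data.

    ``data`` is a pair-level ``DataFrame`` (or :class:`SimulatedCohort`)
    with both traits, or a pre-aggregated ``{pair_type: 16-cell counts}``
    mapping.  Starting values come from univariate fits of each trait's
    marginal concordance tables plus the pooled within-person cross-trait
    tetrachoric correlation (initially attributed to the genetic factor),
    after which L-BFGS-B maximizes the joint likelihood.
    """
    if isinstance(data, dict):
        counts = {k: np.asarray(v, float) for k, v in data.items()}
    else:
        df = getattr(data, "records", data)
        counts = tabulate_pairs_bivariate(df)
    strata = _canonical_strata(counts)
    S = len(strata)
    n_pairs = int(sum(v.sum() for v in counts.values()))
    informative = [s for s in strata if counts[s].sum() > 0]
    if len({relmap.pair(s) for s in informative}) < 2:
        warnings.warn("fewer than two informative relatedness classes: "
                      "A and C are weakly identified", stacklevel=2)

    if start is None:
        fit1 = fit_univariate(_marginal_counts(counts, 1), relmap,
                              compute_ci=False)
        fit2 = fit_univariate(_marginal_counts(counts, 2), relmap,
                              compute_ci=False)
        r_hat = tetrachoric(_within_person_table(counts)).r
        a2_1, c2_1 = fit1.components.a2, fit1.components.c2
        a2_2, c2_2 = fit2.components.a2, fit2.components.c2
        a11 = math.sqrt(max(a2_1, 1e-4))
        a21 = float(np.clip(r_hat / a11, -0.9 * math.sqrt(max(a2_2, 1e-4)),
                            0.9 * math.sqrt(max(a2_2, 1e-4))))
        paths0 = CholeskyPaths(
            a=np.array([[a11, 0.0],
                        [a21, math.sqrt(max(a2_2 - a21 ** 2, 1e-4))]]),
            c=np.array([[math.sqrt(max(c2_1, 1e-4)), 0.0],
                        [0.02, math.sqrt(max(c2_2, 1e-4))]]),
            e=np.array([[math.sqrt(max(1 - a2_1 - c2_1, 1e-4)), 0.0],
                        [0.02, math.sqrt(max(1 - a2_2 - c2_2, 1e-4))]]),
        ).standardized()
        x0 = np.concatenate([
            _internal_from_paths(paths0),
            [fit1.thresholds.thresholds[s] for s in strata],
            [fit2.thresholds.thresholds[s] for s in strata],
        ])
    else:
        x0 = np.asarray(start, float)

    def objective_at(points, shifts):
        def fn(p):
            return -loglik_bivariate(p, counts, relmap, points, shifts)
        return fn

    objective = objective_at(qmc_points, qmc_shifts)
    # coarse-to-fine: a cheap integrator absorbs most optimizer iterations,
    # the full-accuracy objective only polishes
    coarse = minimize(objective_at(256, 2), x0, method="L-BFGS-B",
                      options={"ftol": 1e-13, "gtol": 3e-6, "eps": 3e-6,
                               "maxiter": 500, "maxcor": 30})
    res = minimize(objective, coarse.x, method="L-BFGS-B",
                   options={"ftol": 1e-12, "gtol": 1e-6, "eps": 3e-6,
                            "maxiter": 200, "maxcor": 30})
    if not res.success and "REDUCTION" not in str(res.message):
        res2 = minimize(objective, res.x, method="Nelder-Mead",
                        options={"xatol": 1e-6, "fatol": 1e-8,
                                 "maxiter": 3000})
        if res2.fun < res.fun:
            res = res2
    paths = _paths_from_internal(res.x)
    thresholds = {s: (float(res.x[_N_STRUCT + j]),
                      float(res.x[_N_STRUCT + S + j]))
                  for j, s in enumerate(strata)}
    convergence = {"success": bool(res.success), "iterations": int(res.nit),
                   "nfev": int(res.nfev), "message": str(res.message)}
    vcov = None
    if compute_ci:
        from .liability_model import _information_inverse

        # curvature over steps ~5e-4 is insensitive to the integrator's
        # point budget, so the cheap integrator suffices here
        H = central_hessian(objective_at(256, 2), res.x)
        vcov, note = _information_inverse(H)
        if note:
            convergence["vcov"] = note
    return BivariateFit(paths=paths, thresholds=thresholds, loglik=-res.fun,
                        params=res.x.copy(), vcov=vcov, strata=strata,
                        relmap=relmap, convergence=convergence,
                        n_pairs=n_pairs)


@dataclass(frozen=True)
class CorrelationDecomposition:
    """Additive split of the cross-trait liability correlation."""

    r_total: float
    r_a: float
    r_c: float
    r_e: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_e: float = float("nan")

    def __post_init__(self) -> None:
        if abs(self.r_a + self.r_c + self.r_e - self.r_total) > 1e-8:
            raise ValueError("components must sum to the total correlation")


def decompose_correlation(fit: BivariateFit) -> CorrelationDecomposition:
    """Split the fitted cross-trait correlation into A, C and E contributions.

    On the standardized scale r_total = A12 + C12 + E12.  Confidence
    intervals use the delta method; ``p_e`` is the Wald p-value for the
    null hypothesis that the unique-environment contribution is zero.
    """

    def comp(which):
        def fn(p):
            paths = _paths_from_internal(np.asarray(p, float))
            return getattr(paths, which)[0, 1]
        return fn

    paths = fit.paths
    r_a, r_c, r_e = paths.A[0, 1], paths.C[0, 1], paths.E[0, 1]
    r_total = r_a + r_c + r_e
    ci95: dict[str, tuple[float, float]] = {}
    p_e = float("nan")
    if fit.vcov is None:
        warnings.warn("no parameter covariance available: decomposition "
                      "reported without confidence intervals", stacklevel=2)
    else:
        clip = (-1.0, 1.0)
        for name, which in (("r_a", "A"), ("r_c", "C"), ("r_e", "E")):
            ci95[name] = delta_method_ci(fit, comp(which), clip=clip)

        def total(p):
            paths = _paths_from_internal(np.asarray(p, float))
            return paths.within_person()[0, 1]

        ci95["r_total"] = delta_method_ci(fit, total, clip=clip)
        lo, hi = delta_method_ci(fit, comp("E"), clip=None)
        se = (hi - lo) / (2 * norm.isf(0.025))
        if se > 0:
            p_e = 2.0 * float(norm.sf(abs(r_e) / se))
        else:
            p_e = 1.0
    return CorrelationDecomposition(r_total=float(r_total), r_a=float(r_a),
                                    r_c=float(r_c), r_e=float(r_e),
                                    ci95=ci95, p_e=p_e)
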