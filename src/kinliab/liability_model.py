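"""Univariate ACE liability-threshold models for sibling and twin pair data.

A binary trait is modelled as the indicator that a latent standard-normal
liability exceeds a threshold.  Liability variance is partitioned into
additive-genetic (A), shared-environment (C) and unique-environment (E)
proportions.  Pair resemblance is constrained through a
:class:`RelatednessMap`: the liability correlation of a pair of type *s* is

    r_s = r_A(s) * a2 + r_C(s) * c2

with the classical coefficients r_A = 1 (MZ), 0.5 (DZ and full siblings),
0.25 (half siblings), and shared-environment correlations of 1 for pairs
reared together and census-derived values of 0.83 / 0.03 for maternal /
paternal half siblings.  Parameters are estimated by maximum likelihood on
the per-stratum 2x2 concordance tables, with one threshold per pair-type
stratum (the "relaxed thresholds" design for designs mixing full and half
siblings, whose prevalences differ).

Confidence intervals for the standardized variance proportions are obtained
with the delta method from the observed-information matrix.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from ._mvnorm import bvn_cell_probabilities
from ._numdiff import central_hessian

__all__ = [
    "PAIR_TYPES",
    "RelatednessMap",
    "DEFAULT_RELATEDNESS",
    "VarianceComponents",
    "ThresholdSpec",
    "UnivariateFit",
    "TetrachoricResult",
    "expected_pair_correlation",
    "cell_probabilities",
    "tabulate_pairs",
    "loglik_univariate",
    "fit_univariate",
    "delta_method_ci",
    "tetrachoric",
]

#: Canonical pair-type codes: monozygotic / dizygotic twins, full siblings,
#: maternal / paternal half siblings.
PAIR_TYPES = ("MZ", "DZ", "FS", "MHS", "PHS")


@dataclass(frozen=True)
class RelatednessMap:
    """Assumed additive-genetic and shared-environment pair correlations.

    ``r_a`` carries the expected proportion of additive-genetic effects
    shared by the pair; ``r_c`` the assumed correlation of the shared
    (childhood) environment.  The paternal-half-sibling default of 0.03 and
    the maternal default of 0.83 reflect household co-residence rates from
    Swedish census data.
    """

    r_a: dict[str, float] = field(
        default_factory=lambda: {"MZ": 1.0, "DZ": 0.5, "FS": 0.5,
                                 "MHS": 0.25, "PHS": 0.25}
    )
    r_c: dict[str, float] = field(
        default_factory=lambda: {"MZ": 1.0, "DZ": 1.0, "FS": 1.0,
                                 "MHS": 0.83, "PHS": 0.03}
    )

    def __post_init__(self) -> None:
        for d in (self.r_a, self.r_c):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"relatedness coefficient {k}={v} outside [0, 1]")
        if set(self.r_a) != set(self.r_c):
            raise ValueError("r_a and r_c must cover the same pair types")

    def pair(self, pair_type: str) -> tuple[float, float]:
        """Return ``(r_A, r_C)`` for a pair type, or raise ``ValueError``."""
        try:
            return self.r_a[pair_type], self.r_c[pair_type]
        except KeyError:
            raise ValueError(f"unknown pair type {pair_type!r}; "
                             f"known: {sorted(self.r_a)}") from None

    def with_override(self, pair_type: str, r_a: float | None = None,
                      r_c: float | None = None) -> "RelatednessMap":
        ra = dict(self.r_a)
        rc = dict(self.r_c)
        if r_a is not None:
            ra[pair_type] = r_a
        if r_c is not None:
            rc[pair_type] = r_c
        return RelatednessMap(ra, rc)


DEFAULT_RELATEDNESS = RelatednessMap()


@dataclass(frozen=True)
class VarianceComponents:
    """Standardized liability-variance proportions (a2 + c2 + e2 = 1)."""

    a2: float
    c2: float
    e2: float

    def __post_init__(self) -> None:
        for name in ("a2", "c2", "e2"):
            v = getattr(self, name)
            if not -1e-10 <= v <= 1.0 + 1e-10:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-8:
            raise ValueError("variance proportions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.a2, self.c2, self.e2])


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-stratum liability thresholds (standard-normal units).

    ``covariate_slopes`` optionally holds probit regression slopes that
    shift the threshold linearly in covariates: t_i = t0 + beta' x_i.
    """

    thresholds: dict[str, float]
    covariate_slopes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.thresholds.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite threshold for stratum {k!r}")


@dataclass
class UnivariateFit:
    """Result of a univariate ACE liability-threshold fit."""

    components: VarianceComponents
    thresholds: ThresholdSpec
    loglik: float
    params: np.ndarray           # free parameters [z_a, (z_c,), t_1..t_S]
    vcov: np.ndarray | None      # observed-information covariance of params
    ci95: dict[str, tuple[float, float]]
    strata: tuple[str, ...]
    relmap: RelatednessMap
    convergence: dict
    c2_fixed: bool = False
    boundary: bool = False
    n_pairs: int = 0

    def component_ci(self, name: str) -> tuple[float, float]:
        return self.ci95[name]


def expected_pair_correlation(vc: VarianceComponents, pair_type: str,
                              relmap: RelatednessMap = DEFAULT_RELATEDNESS) -> float:
    """Model-implied liability correlation for one pair type."""
    r_a, r_c = relmap.pair(pair_type)
    return r_a * vc.a2 + r_c * vc.c2


def cell_probabilities(r: float, t1: float, t2: float) -> np.ndarray:
    """Bivariate-normal rectangle probabilities of the four concordance cells.

    Order: (both above, first only, second only, neither).  Sums to 1.
    """
    if not np.isfinite(r) or abs(r) > 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r!r}")
    return bvn_cell_probabilities(r, t1, t2)


# ---------------------------------------------------------------------------
# internal (unconstrained) parameterization of (a2, c2, e2)
# ---------------------------------------------------------------------------
# Components are squared path coefficients normalized to sum one, with the
# E path fixed at raw value 1 so the map is locally one-to-one:
#   a2 = z_a^2 / D,  c2 = z_c^2 / D,  e2 = 1 / D,  D = 1 + z_a^2 + z_c^2.
# Non-negativity is automatic and c2 = 0 lies at the smooth point z_c = 0,
# where the delta-method interval for c2 collapses to zero width.


def _components_from_internal(z_a: float, z_c: float) -> VarianceComponents:
    D = 1.0 + z_a * z_a + z_c * z_c
    return VarianceComponents(z_a * z_a / D, z_c * z_c / D, 1.0 / D)


def _internal_from_components(a2: float, c2: float) -> tuple[float, float]:
    e2 = max(1.0 - a2 - c2, 1e-4)
    return math.sqrt(max(a2, 0.0) / e2), math.sqrt(max(c2, 0.0) / e2)


def _canonical_strata(keys) -> tuple[str, ...]:
    order = {pt: i for i, pt in enumerate(PAIR_TYPES)}
    return tuple(sorted(keys, key=lambda k: (order.get(k, len(order)), k)))


def tabulate_pairs(pairs: pd.DataFrame, trait: int = 1) -> dict[str, np.ndarray]:
    """Aggregate a pair table into per-pair-type 4-cell concordance counts.

    Cell order per stratum: (1,1), (1,0), (0,1), (0,0) for
    (member 1, member 2) trait indicators.
    """
    y1 = pairs[f"trait{trait}_m1"].to_numpy(int)
    y2 = pairs[f"trait{trait}_m2"].to_numpy(int)
    cell = (1 - y1) * 2 + (1 - y2)  # 0 -> (1,1), 3 -> (0,0)
    out: dict[str, np.ndarray] = {}
    for pt, idx in pairs.groupby("pair_type").indices.items():
        counts = np.bincount(cell[idx], minlength=4).astype(float)
        out[str(pt)] = counts
    return out


def loglik_univariate(params: np.ndarray, cell_counts: dict[str, np.ndarray],
                      relmap: RelatednessMap = DEFAULT_RELATEDNESS,
                      c2_fixed: bool = False) -> float:
    """Multinomial log-likelihood of per-stratum concordance cells.

    ``params`` is ``[z_a, z_c, t_1, ..., t_S]`` (or ``[z_a, t_1, ...]``
    when ``c2_fixed``), with strata in canonical pair-type order.  Returns
    ``-inf`` when a cell with positive count has probability zero.
    """
    params = np.asarray(params, float)
    strata = _canonical_strata(cell_counts)
    if c2_fixed:
        z_a, z_c = params[0], 0.0
        thresholds = params[1:]
    else:
        z_a, z_c = params[0], params[1]
        thresholds = params[2:]
    if len(thresholds) != len(strata):
        raise ValueError("parameter vector length does not match strata")
    vc = _components_from_internal(z_a, z_c)
    ll = 0.0
    for t, s in zip(thresholds, strata):
        n = np.asarray(cell_counts[s], float)
        if n.sum() == 0:
            continue
        r = expected_pair_correlation(vc, s, relmap)
        p = bvn_cell_probabilities(min(r, 1.0), t, t)
        pos = n > 0
        if np.any(p[pos] <= 0.0):
            return -np.inf
        ll += float(np.sum(n[pos] * np.log(p[pos])))
    return ll


_DEFAULT_STARTS = ((0.3, 0.3), (0.6, 0.05), (0.1, 0.5), (0.8, 0.1), (0.02, 0.02))


def _covariate_groups(pairs: pd.DataFrame, trait: int,
                      covariates: tuple[str, ...], bins: int = 4):
    """Aggregate pairs into (stratum, member-covariate-class) cell counts.

    Covariates use the same centered coding as the generator; birth year is
    quantile-binned (class value = bin mean) so the aggregated likelihood
    stays exact up to within-bin variation.
    """
    from .synthetic_data import covariate_design

    cols = {}
    for m in (1, 2):
        design = covariate_design(pairs[f"sex_m{m}"].to_numpy(),
                                  pairs[f"birthyear_m{m}"].to_numpy())
        for c in covariates:
            if c not in design:
                raise ValueError(f"unknown covariate {c!r}")
            v = design[c]
            if c == "birthyear":
                edges = np.quantile(v, np.linspace(0, 1, bins + 1))
                idx = np.clip(np.searchsorted(edges, v, side="right") - 1,
                              0, bins - 1)
                v = np.array([v[idx == k].mean() if np.any(idx == k) else 0.0
                              for k in range(bins)])[idx]
            cols[f"{c}_m{m}"] = v
    work = pd.DataFrame(cols)
    work["pair_type"] = pairs["pair_type"].to_numpy()
    y1 = pairs[f"trait{trait}_m1"].to_numpy(int)
    y2 = pairs[f"trait{trait}_m2"].to_numpy(int)
    work["cell"] = (1 - y1) * 2 + (1 - y2)
    keys = (["pair_type"] + [f"{c}_m1" for c in covariates]
            + [f"{c}_m2" for c in covariates])
    grouped = work.groupby(keys + ["cell"]).size().unstack("cell",
                                                           fill_value=0)
    grouped = grouped.reindex(columns=range(4), fill_value=0).reset_index()
    strata = _canonical_strata(set(grouped["pair_type"]))
    s_idx = grouped["pair_type"].map({s: i for i, s in enumerate(strata)})
    x1 = grouped[[f"{c}_m1" for c in covariates]].to_numpy(float)
    x2 = grouped[[f"{c}_m2" for c in covariates]].to_numpy(float)
    counts = grouped[list(range(4))].to_numpy(float)
    return strata, s_idx.to_numpy(int), x1, x2, counts


def _loglik_covariate(params, strata, s_idx, x1, x2, counts, relmap,
                      c2_fixed: bool) -> float:
    head = 1 if c2_fixed else 2
    z_a = params[0]
    z_c = 0.0 if c2_fixed else params[1]
    S = len(strata)
    thresholds = params[head:head + S]
    betas = params[head + S:]
    vc = _components_from_internal(z_a, z_c)
    rs = np.array([min(expected_pair_correlation(vc, s, relmap), 1.0)
                   for s in strata])
    t1 = thresholds[s_idx] + x1 @ betas
    t2 = thresholds[s_idx] + x2 @ betas
    ll = 0.0
    for g in range(len(counts)):
        n = counts[g]
        p = bvn_cell_probabilities(rs[s_idx[g]], t1[g], t2[g])
        pos = n > 0
        if np.any(p[pos] <= 0.0):
            return -np.inf
        ll += float(np.sum(n[pos] * np.log(p[pos])))
    return ll


def _coerce_counts(data, trait: int) -> tuple[dict[str, np.ndarray], int]:
    if isinstance(data, dict):
        counts = {k: np.asarray(v, float) for k, v in data.items()}
    else:
        df = getattr(data, "records", data)
        counts = tabulate_pairs(df, trait=trait)
    n_pairs = int(sum(v.sum() for v in counts.values()))
    return counts, n_pairs


def fit_univariate(data, relmap: RelatednessMap = DEFAULT_RELATEDNESS,
                   trait: int = 1, fix_c2: bool | None = None,
                   warm_start: np.ndarray | None = None,
                   covariates: tuple[str, ...] | None = None,
                   compute_ci: bool = True) -> UnivariateFit:
    """Maximum-likelihood univariate ACE fit to pair concordance data.

    ``data`` may be a pair-level ``DataFrame`` (columns ``pair_type``,
    ``trait{k}_m1``, ``trait{k}_m2``), a :class:`SimulatedCohort`, or a
    pre-aggregated ``{pair_type: 4-cell counts}`` mapping.

    The optimizer runs Nelder-Mead from five fixed starting points and
    polishes the best with L-BFGS-B (finite-difference gradients); with a
    ``warm_start`` vector only the polish step runs, which is the fast path
    for bootstrap replication.

    ``covariates`` (any of ``"sex"``, ``"birthyear"``) adds probit threshold
    regression: each member's threshold becomes ``t_stratum + beta' x``,
    with one slope vector shared across strata.  Requires pair-level input.
    """
    cov_groups = None
    if covariates:
        covariates = tuple(covariates)
        df = getattr(data, "records", data)
        if not isinstance(df, pd.DataFrame):
            raise ValueError("covariate adjustment needs pair-level data")
        cov_groups = _covariate_groups(df, trait, covariates)
    counts, n_pairs = _coerce_counts(data, trait)
    strata = _canonical_strata(counts)
    if n_pairs == 0:
        raise ValueError("no pairs to fit")

    # a2 and c2 are separable only if two strata load differently on A vs C
    coeffs = {relmap.pair(s) for s in strata if counts[s].sum() > 0}
    if fix_c2 is None:
        fix_c2 = False
        if len(coeffs) < 2:
            warnings.warn(
                "only one informative relatedness class: a2 and c2 are not "
                "jointly identifiable; fixing c2 = 0", stacklevel=2)
            fix_c2 = True

    t0 = []
    for s in strata:
        n = counts[s]
        prev = (2 * n[0] + n[1] + n[2]) / max(2 * n.sum(), 1.0)
        t0.append(norm.isf(np.clip(prev, 1e-6, 1 - 1e-6)))
    t0 = np.asarray(t0)

    n_cov = len(covariates) if covariates else 0
    if cov_groups is not None:
        g_strata, s_idx, x1, x2, g_counts = cov_groups

        def objective(p):
            return -_loglik_covariate(p, g_strata, s_idx, x1, x2, g_counts,
                                      relmap, c2_fixed=fix_c2)
    else:
        def objective(p):
            return -loglik_univariate(p, counts, relmap, c2_fixed=fix_c2)

    candidates: list[np.ndarray] = []
    if warm_start is not None:
        candidates.append(np.asarray(warm_start, float))
    else:
        for a2s, c2s in _DEFAULT_STARTS:
            z_a, z_c = _internal_from_components(a2s, c2s)
            head = [z_a] if fix_c2 else [z_a, z_c]
            candidates.append(np.concatenate([head, t0, np.zeros(n_cov)]))

    best = None
    best_success = False
    for x0 in candidates:
        stage_success = False
        if warm_start is None:
            nm = minimize(objective, x0, method="Nelder-Mead",
                          options={"xatol": 1e-6, "fatol": 1e-8,
                                   "maxiter": 4000})
            x0 = nm.x
            stage_success = bool(nm.success)
        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"ftol": 1e-12, "gtol": 1e-8, "eps": 1e-6})
        # a failed line search at the optimum is still convergence if the
        # derivative-free stage already converged there
        stage_success = bool(res.success) or stage_success
        if best is None or res.fun < best.fun:
            best = res
            best_success = stage_success

    head = 1 if fix_c2 else 2
    z_a = best.x[0]
    z_c = 0.0 if fix_c2 else best.x[1]
    vc = _components_from_internal(z_a, z_c)
    slopes = (dict(zip(covariates, best.x[head + len(strata):]))
              if n_cov else {})
    thresholds = ThresholdSpec(
        dict(zip(strata, best.x[head:head + len(strata)])),
        covariate_slopes=slopes)
    convergence = {"success": best_success, "iterations": int(best.nit),
                   "nfev": int(best.nfev), "message": str(best.message)}

    vcov = None
    ci95: dict[str, tuple[float, float]] = {}
    if compute_ci:
        H = central_hessian(objective, best.x)
        vcov, note = _information_inverse(H)
        if note:
            convergence["vcov"] = note

    fit = UnivariateFit(
        components=vc, thresholds=thresholds, loglik=-best.fun,
        params=best.x.copy(), vcov=vcov, ci95=ci95, strata=strata,
        relmap=relmap, convergence=convergence, c2_fixed=fix_c2,
        boundary=vc.c2 < 1e-6 or vc.a2 < 1e-6, n_pairs=n_pairs,
    )
    if vcov is not None:
        for name, fn in _component_transforms(fix_c2).items():
            ci95[name] = delta_method_ci(fit, fn)
    return fit


def _information_inverse(H: np.ndarray) -> tuple[np.ndarray | None, str | None]:
    """Invert an observed-information matrix, tolerating flat or boundary
    directions by zeroing non-positive-curvature eigendirections."""
    if not np.all(np.isfinite(H)):
        return None, "non-finite observed information"
    w, V = np.linalg.eigh(np.asarray(H, float))
    cutoff = 1e-10 * max(np.abs(w).max(), 1.0)
    winv = np.where(w > cutoff, 1.0 / np.where(w > cutoff, w, 1.0), 0.0)
    vcov = (V * winv) @ V.T
    note = None
    if np.any(w <= cutoff):
        note = ("information matrix not positive definite (boundary or flat "
                "direction); that direction's variance set to zero")
    return vcov, note


def _component_transforms(c2_fixed: bool):
    def a2(p):
        z_c = 0.0 if c2_fixed else p[1]
        return _components_from_internal(p[0], z_c).a2

    def c2(p):
        z_c = 0.0 if c2_fixed else p[1]
        return _components_from_internal(p[0], z_c).c2

    def e2(p):
        z_c = 0.0 if c2_fixed else p[1]
        return _components_from_internal(p[0], z_c).e2

    return {"a2": a2, "c2": c2, "e2": e2}


def delta_method_ci(fit, transform, level: float = 0.95,
                    clip: tuple[float, float] | None = (0.0, 1.0),
                    params: np.ndarray | None = None,
                    vcov: np.ndarray | None = None) -> tuple[float, float]:
    """Delta-method confidence interval for ``transform(params)``.

    ``fit`` is any object with ``params`` and ``vcov`` attributes (pass
    ``fit=None`` and supply both arrays explicitly to use raw inputs).
    The gradient is computed by central differences; the interval is
    ``g(theta) +- z * sqrt(grad' V grad)``, truncated to ``clip``.
    """
    if fit is not None:
        params = np.asarray(fit.params, float)
        vcov = fit.vcov
    else:
        params = np.asarray(params, float)
    if vcov is None or not np.all(np.isfinite(vcov)):
        raise ValueError(
            "parameter covariance unavailable or singular; consider a "
            "profile-likelihood interval instead")
    g0 = float(transform(params))
    grad = np.zeros_like(params)
    for i in range(len(params)):
        h = 1e-6 * max(1.0, abs(params[i]))
        up = params.copy(); up[i] += h
        dn = params.copy(); dn[i] -= h
        grad[i] = (float(transform(up)) - float(transform(dn))) / (2 * h)
    var = float(grad @ np.asarray(vcov) @ grad)
    se = math.sqrt(max(var, 0.0))
    z = norm.isf((1.0 - level) / 2.0)
    lo, hi = g0 - z * se, g0 + z * se
    if clip is not None:
        lo, hi = max(lo, clip[0]), min(hi, clip[1])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# tetrachoric correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TetrachoricResult:
    r: float
    se: float
    t1: float
    t2: float
    loglik: float
    boundary: bool = False


def tetrachoric(table: np.ndarray) -> TetrachoricResult:
    """ML tetrachoric correlation of a 2x2 table of dichotomized counts.

    ``table[i, j]`` counts pairs with variable 1 in state *i* and variable 2
    in state *j*, state 0 meaning "above threshold".  The full 3-parameter
    multinomial likelihood is maximized over (r, t1, t2); the standard error
    of r comes from the observed information (delta method through the
    ``tanh`` parameterization that keeps r inside (-1, 1)).
    """
    n = np.asarray(table, float)
    if n.shape != (2, 2) or np.any(n < 0):
        raise ValueError("table must be a non-negative 2x2 count matrix")
    if np.any(n.sum(axis=0) == 0) or np.any(n.sum(axis=1) == 0):
        raise ValueError("tetrachoric correlation undefined for a zero margin")
    boundary = n[0, 1] == 0 or n[1, 0] == 0
    if boundary:
        warnings.warn("zero off-diagonal cell: tetrachoric estimate lies at "
                      "the boundary r -> 1", stacklevel=2)
    p1 = n[0].sum() / n.sum()
    p2 = n[:, 0].sum() / n.sum()
    t1_0 = norm.isf(np.clip(p1, 1e-9, 1 - 1e-9))
    t2_0 = norm.isf(np.clip(p2, 1e-9, 1 - 1e-9))

    flat = np.array([n[0, 0], n[0, 1], n[1, 0], n[1, 1]])

    def neg_ll(x):
        r = math.tanh(x[0])
        p = bvn_cell_probabilities(r, x[1], x[2])
        if np.any(p[flat > 0] <= 0):
            return np.inf
        return -float(np.sum(flat[flat > 0] * np.log(p[flat > 0])))

    x0 = np.array([0.0, t1_0, t2_0])
    res = minimize(neg_ll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    res = minimize(neg_ll, res.x, method="L-BFGS-B",
                   bounds=[(-7.0, 7.0), (-8.0, 8.0), (-8.0, 8.0)],
                   options={"ftol": 1e-13})
    r = math.tanh(res.x[0])
    se = float("nan")
    try:
        H = central_hessian(neg_ll, res.x, rel_step=1e-4)
        v = np.linalg.pinv(H)[0, 0]
        se = math.sqrt(max(v, 0.0)) * (1.0 - r * r)  # d tanh/dz
    except Exception:  # pragma: no cover - degenerate tables only
        pass
    return TetrachoricResult(r=r, se=se, t1=float(res.x[1]), t2=float(res.x[2]),
                             loglik=-float(res.fun), boundary=bool(boundary))
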