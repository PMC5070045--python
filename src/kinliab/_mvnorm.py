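"""Deterministic multivariate-normal rectangle probabilities.

Two primitives back every liability-threshold likelihood in the package:

* :func:`bvn_upper` — the 2-D upper-orthant probability, computed by
  adaptive 1-D quadrature of the conditional form
  ``P(X>t1, Y>t2) = int_{t1}^inf phi(x) Phi((r x - t2)/sqrt(1-r^2)) dx``.
* :func:`mvn_rectangle_masses` — batched rectangle probabilities of a
  zero-mean multivariate normal, via the Genz sequential-conditioning
  transformation integrated with scrambled Sobol points at a fixed
  internal seed.  Deterministic for a given point budget, so objective
  functions built on it are smooth and reproducible.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

__all__ = ["bvn_upper", "bvn_cell_probabilities", "mvn_rectangle_masses"]

_SOBOL_SEED = 761974  # fixed: rectangle masses must be reproducible
_U_EPS = 1e-15


def bvn_upper(r: float, t1: float, t2: float) -> float:
    """``P(X > t1, Y > t2)`` for a standard bivariate normal with correlation *r*.

    Raises ``ValueError`` for ``|r| > 1``.  The degenerate cases ``r = +-1``
    reduce to one-dimensional normal tail probabilities.
    """
    if not np.isfinite(r) or abs(r) > 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r!r}")
    if r == 1.0:
        return float(ndtr(-max(t1, t2)))
    if r == -1.0:
        # X > t1 and -X > t2  <=>  t1 < X < -t2
        return float(max(0.0, ndtr(-t2) - ndtr(t1)))
    if r == 0.0:
        return float(ndtr(-t1) * ndtr(-t2))
    den = math.sqrt(1.0 - r * r)

    def integrand(x: float) -> float:
        return math.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi) * ndtr(
            (r * x - t2) / den
        )

    val, _ = integrate.quad(integrand, t1, np.inf, epsabs=1e-13, epsrel=1e-11,
                            limit=200)
    return float(min(max(val, 0.0), 1.0))


def bvn_cell_probabilities(r: float, t1: float, t2: float) -> np.ndarray:
    """Probabilities of the four cells of a doubly dichotomized bivariate normal.

    Order: (both above, first only above, second only above, neither above).
    """
    p11 = bvn_upper(r, t1, t2)
    p1 = float(ndtr(-t1))
    p2 = float(ndtr(-t2))
    p = np.array([p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11])
    return np.clip(p, 0.0, 1.0)


_point_cache: dict[tuple[int, int, int], np.ndarray] = {}


def _sobol_shifts(n: int, nshift: int, dim: int) -> np.ndarray:
    """Cached scrambled-Sobol point sets, shape ``(nshift, n, dim)``."""
    key = (n, nshift, dim)
    pts = _point_cache.get(key)
    if pts is None:
        rng = np.random.default_rng(_SOBOL_SEED)
        m = int(round(math.log2(n)))
        if 2 ** m != n:
            raise ValueError("point count must be a power of two")
        pts = np.stack(
            [qmc.Sobol(d=dim, scramble=True, seed=rng).random_base2(m)
             for _ in range(nshift)]
        )
        _point_cache[key] = pts
    return pts


def _psd_cholesky(sigma: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, tolerating semi-definite input via a tiny ridge."""
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(sigma)
        if w.min() < -1e-8:
            raise ValueError(
                f"covariance matrix is not positive semi-definite "
                f"(min eigenvalue {w.min():.3e})"
            ) from None
        ridge = max(1e-12, -w.min() * 2 + 1e-12)
        return np.linalg.cholesky(sigma + ridge * np.eye(sigma.shape[0]))


def mvn_rectangle_masses(
    sigma: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    n: int = 1024,
    nshift: int = 8,
    return_error: bool = False,
):
    """Batched rectangle probabilities of ``N(0, sigma)``.

    Parameters
    ----------
    sigma
        ``(d, d)`` covariance matrix (PSD; unit diagonal not required), or
        a ``(P, d, d)`` stack giving one covariance per rectangle.
    lower, upper
        ``(P, d)`` arrays of rectangle limits; ``+-inf`` allowed.
    n, nshift
        Sobol points per randomization and number of independent
        scramblings.  The error estimate is ``3 * sem`` across scramblings.

    Returns the ``(P,)`` probability vector, plus the error vector when
    ``return_error`` is true.
    """
    sigma = np.asarray(sigma, float)
    lower = np.atleast_2d(np.asarray(lower, float))
    upper = np.atleast_2d(np.asarray(upper, float))
    P = lower.shape[0]
    if sigma.ndim == 2:
        d = sigma.shape[0]
        L = np.broadcast_to(_psd_cholesky(sigma), (P, d, d))
    else:  # one covariance per rectangle
        d = sigma.shape[1]
        if sigma.shape[0] != P:
            raise ValueError("batched sigma must match the number of rectangles")
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            L = np.stack([_psd_cholesky(s) for s in sigma])
    if lower.shape != upper.shape or lower.shape[1] != d:
        raise ValueError("limit arrays must have shape (P, d)")
    pts = _sobol_shifts(n, nshift, d - 1)
    ests = np.empty((nshift, P))
    d0 = ndtr(lower[:, 0] / L[:, 0, 0])[:, None]
    e0 = ndtr(upper[:, 0] / L[:, 0, 0])[:, None]
    for k in range(nshift):
        w = pts[k]  # (n, d-1)
        f = np.broadcast_to(e0 - d0, (P, n)).copy()
        dlo, dhi = np.broadcast_to(d0, (P, n)), np.broadcast_to(e0, (P, n))
        ys = np.empty((d - 1, P, n))
        for i in range(1, d):
            u = dlo + w[None, :, i - 1] * (dhi - dlo)
            ys[i - 1] = ndtri(np.clip(u, _U_EPS, 1.0 - _U_EPS))
            mean_i = np.einsum("jp,jpn->pn", L[:, i, :i].T, ys[:i])
            dlo = ndtr((lower[:, i, None] - mean_i) / L[:, i, i, None])
            dhi = ndtr((upper[:, i, None] - mean_i) / L[:, i, i, None])
            f = f * (dhi - dlo)
        ests[k] = f.mean(axis=1)
    value = ests.mean(axis=0)
    value = np.clip(value, 0.0, 1.0)
    if return_error:
        err = 3.0 * ests.std(axis=0, ddof=1) / math.sqrt(nshift)
        return value, err
    return value
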