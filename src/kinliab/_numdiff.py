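"""Central-difference derivatives sized for large-magnitude log-likelihoods.

A log-likelihood of magnitude ~1e5 evaluated to ~1e-10 absolute precision
needs Hessian steps of order 1e-4..1e-3: the default steps of generic
numerical differentiators sit below the floating-point noise floor along
weakly curved (nearly flat) parameter directions and can return indefinite
curvature matrices.
"""
from __future__ import annotations

import numpy as np

__all__ = ["central_hessian", "central_gradient"]


def central_gradient(f, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    for i in range(len(x)):
        h = rel_step * max(1.0, abs(x[i]))
        up, dn = x.copy(), x.copy()
        up[i] += h
        dn[i] -= h
        g[i] = (float(f(up)) - float(f(dn))) / (2.0 * h)
    return g


def central_hessian(f, x: np.ndarray, rel_step: float = 5e-4) -> np.ndarray:
    """Symmetric central-difference Hessian with per-coordinate steps
    ``rel_step * max(1, |x_i|)``."""
    x = np.asarray(x, float)
    n = len(x)
    steps = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((n, n))
    f0 = float(f(x))
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += steps[i]
        xm[i] -= steps[i]
        H[i, i] = (float(f(xp)) - 2.0 * f0 + float(f(xm))) / steps[i] ** 2
        for j in range(i + 1, n):
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[[i, j]] += steps[[i, j]]
            xmm[[i, j]] -= steps[[i, j]]
            xpm[i] += steps[i]
            xpm[j] -= steps[j]
            xmp[i] -= steps[i]
            xmp[j] += steps[j]
            H[i, j] = H[j, i] = (
                float(f(xpp)) - float(f(xpm)) - float(f(xmp)) + float(f(xmm))
            ) / (4.0 * steps[i] * steps[j])
    return H
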