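"""Shrinkage operators: soft thresholding, singular-value shrinkage, and the
minimax concave penalty (MCP) driven spectral shrink used on Tucker factors.

MCP is a folded-concave surrogate for rank: it grows like ``lam * |t|`` near
zero but flattens at ``a * lam**2 / 2`` once ``|t| >= a * lam``, so large
singular values incur no further penalty — the source of the (near)
unbiasedness that the nuclear norm lacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MCPParams",
    "soft_threshold",
    "svt",
    "mcp_penalty",
    "mcp_derivative",
    "mcp_svd_shrink",
]


@dataclass(frozen=True)
class MCPParams:
    """MCP threshold scale ``lam`` and concavity constant ``a`` (> 1).

    ``lam`` defaults to 1: in the factor update only the product of the outer
    regularization weight and ``lam`` is identifiable, so the outer weight
    alone sets the shrinkage strength.
    """

    lam: float = 1.0
    a: float = 2.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.a <= 1:
            raise ValueError("a must be > 1")


def soft_threshold(x, delta: float):
    """Elementwise soft thresholding: ``sign(x) * max(|x| - delta, 0)``."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - delta, 0.0)


def svt(x: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value shrinkage (prox of ``tau * ||.||_*``)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    return (u * np.maximum(s - tau, 0.0)) @ vt


def mcp_penalty(t, p: MCPParams):
    """MCP value: ``lam|t| - t^2/(2a)`` below ``a*lam``, then flat at ``a*lam^2/2``."""
    t = np.abs(np.asarray(t, dtype=float))
    flat = 0.5 * p.a * p.lam**2
    val = np.where(t >= p.a * p.lam, flat, p.lam * t - t**2 / (2.0 * p.a))
    return val if val.ndim else float(val)


def mcp_derivative(t, p: MCPParams):
    """d/dt of the MCP on t >= 0: ``max(lam - t/a, 0)``; zero in the flat region."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.maximum(p.lam - t / p.a, 0.0)
    return out if out.ndim else float(out)


def mcp_svd_shrink(
    a_mat: np.ndarray,
    lam1: float,
    p: MCPParams,
    w3: float,
    sigma_prev: np.ndarray | None = None,
) -> np.ndarray:
    """Spectral shrink solving the MCP-penalized factor subproblem.

    Minimizes (a local linear majorization of)

        lam1 * sum_j P_lam(sigma_j(U)) + (w3 / 2) * ||U - a_mat||_F^2

    by soft-thresholding the j-th singular value of ``a_mat`` at
    ``(lam1 / w3) * P'_lam(sigma_prev_j)``.  With ``sigma_prev`` absent the
    majorization point is zero, every threshold equals ``lam1 * lam / w3``
    and the update reduces to plain :func:`svt` — the constant-threshold
    one-step form.  With ``sigma_prev`` from the previous iterate, singular
    values already in the flat MCP region (>= a*lam) get zero threshold and
    pass through unshrunk (the unbiasedness property).

    Since P'_lam is nonincreasing and singular values are sorted descending,
    the per-index thresholds are nondecreasing, which is exactly the regime
    where weighted singular-value shrinkage is the closed-form minimizer of
    the weighted nuclear-norm subproblem.
    """
    if w3 <= 0:
        raise ValueError("w3 must be > 0")
    if lam1 < 0:
        raise ValueError("lam1 must be >= 0")
    a_mat = np.asarray(a_mat, dtype=float)
    u, s, vt = np.linalg.svd(a_mat, full_matrices=False)
    if sigma_prev is None or len(np.atleast_1d(sigma_prev)) == 0:
        weights = np.full_like(s, p.lam)
    else:
        sp = np.sort(np.abs(np.atleast_1d(np.asarray(sigma_prev, dtype=float))))[::-1]
        if len(sp) < len(s):
            # missing entries majorize at zero, where P' = lam
            sp = np.concatenate([sp, np.zeros(len(s) - len(sp))])
        weights = mcp_derivative(sp[: len(s)], p)
    thresh = (lam1 / w3) * np.atleast_1d(weights)
    return (u * np.maximum(s - thresh, 0.0)) @ vt
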