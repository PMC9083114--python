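"""Degradation and finite-difference operators with exact adjoints.

Two linear operator pairs drive the reconstruction model:

* ``blur_downsample`` / ``blur_downsample_adjoint`` — the forward observation
  operator ``DS`` (separable Gaussian blur ``S`` followed by integer
  decimation ``D``) and its transpose.  The blur uses half-sample symmetric
  ("reflect") boundary handling, under which a symmetric kernel is exactly
  self-adjoint, so ``(DS)^T = S^T D^T = S(zero-fill)``.
* ``tv_diff`` / ``tv_diff_adjoint`` — the weighted 3D forward-difference
  operator behind the anisotropic total-variation term, with Neumann
  (zero last difference) boundaries, and its negative-divergence adjoint.

Both pairs satisfy <A x, y> == <x, A^T y> to machine precision; the test
suite checks this on randomized draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "DegradationSpec",
    "TVWeights",
    "blur_downsample",
    "blur_downsample_adjoint",
    "tv_diff",
    "tv_diff_adjoint",
    "tv_value",
]


def _as_triple(v) -> tuple:
    if np.isscalar(v):
        return (v, v, v)
    t = tuple(v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3 sequence, got {v!r}")
    return t


@dataclass(frozen=True)
class DegradationSpec:
    """Forward model ``Y = D S X``: Gaussian blur then decimation.

    Parameters
    ----------
    blur_sigma : float or triple
        Gaussian std in voxels per axis; 0 disables the blur.
    down_factor : int or triple
        Decimation factor per axis; every ``factor``-th voxel is kept,
        starting at index 0.
    kernel_radius : int, optional
        Truncation radius of the blur kernel in voxels.  Defaults to
        ``ceil(3 * sigma)``; the truncated kernel is renormalized to sum 1
        so constants are preserved.
    boundary : str
        Padding rule for the blur; 'reflect' (half-sample symmetric) keeps
        the blur self-adjoint and is the only mode with an exact adjoint
        implemented here.
    """

    blur_sigma: float | tuple = 1.0
    down_factor: int | tuple = 2
    kernel_radius: int | None = None
    boundary: str = "reflect"

    def __post_init__(self):
        for s in _as_triple(self.blur_sigma):
            if s < 0:
                raise ValueError("blur_sigma must be >= 0")
        for f in _as_triple(self.down_factor):
            if int(f) != f or f < 1:
                raise ValueError("down_factor must be a positive integer")
        if self.boundary != "reflect":
            raise ValueError("only 'reflect' boundary is supported")
        if self.kernel_radius is not None:
            need = max(math.ceil(3 * s) for s in _as_triple(self.blur_sigma))
            if self.kernel_radius < need:
                raise ValueError(f"kernel_radius must be >= ceil(3*sigma) = {need}")

    @property
    def sigmas(self) -> tuple:
        return _as_triple(self.blur_sigma)

    @property
    def factors(self) -> tuple:
        return tuple(int(f) for f in _as_triple(self.down_factor))

    def radius_for(self, sigma: float) -> int:
        if self.kernel_radius is not None:
            return int(self.kernel_radius)
        return max(1, math.ceil(3 * sigma))

    def lr_shape(self, hr_shape: tuple) -> tuple:
        return tuple(-(-s // f) for s, f in zip(hr_shape, self.factors))


def _blur(x: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    out = np.asarray(x, dtype=float)
    for axis, sigma in enumerate(spec.sigmas):
        if sigma > 0:
            out = gaussian_filter1d(
                out, sigma, axis=axis, mode="reflect", radius=spec.radius_for(sigma)
            )
    return out


def blur_downsample(x: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Apply the forward observation operator ``DS`` to an HR volume."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected a 3rd-order volume")
    if x.size == 0:
        raise ValueError("empty volume")
    for s, f in zip(x.shape, spec.factors):
        if f > s:
            raise ValueError(f"down_factor {f} exceeds extent {s}")
    f1, f2, f3 = spec.factors
    return _blur(x, spec)[::f1, ::f2, ::f3]


def blur_downsample_adjoint(
    y: np.ndarray, spec: DegradationSpec, hr_shape: tuple
) -> np.ndarray:
    """Exact transpose ``(DS)^T``: zero-fill upsampling then the (self-adjoint) blur."""
    y = np.asarray(y, dtype=float)
    hr_shape = tuple(int(s) for s in hr_shape)
    if y.shape != spec.lr_shape(hr_shape):
        raise ValueError(
            f"LR shape {y.shape} inconsistent with HR shape {hr_shape} "
            f"under factors {spec.factors}"
        )
    f1, f2, f3 = spec.factors
    up = np.zeros(hr_shape, dtype=float)
    up[::f1, ::f2, ::f3] = y
    return _blur(up, spec)


@dataclass(frozen=True)
class TVWeights:
    """Per-mode weights of the anisotropic 3D total variation."""

    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0

    def __post_init__(self):
        w = self.as_tuple()
        if any(not np.isfinite(v) or v < 0 for v in w):
            raise ValueError("TV weights must be finite and nonnegative")
        if all(v == 0 for v in w):
            raise ValueError("TV weights must not all be zero")

    def as_tuple(self) -> tuple:
        return (self.w1, self.w2, self.w3)

    @property
    def alphas(self) -> tuple:
        """Per-mode shares w_n / sum(w); used to split the TV threshold."""
        total = sum(self.as_tuple())
        return tuple(v / total for v in self.as_tuple())


def tv_diff(x: np.ndarray, w: TVWeights) -> np.ndarray:
    """Weighted forward differences along each mode, stacked on a new axis 0.

    Component ``d`` is ``w_d * (x[i+1] - x[i])`` along mode ``d`` with the
    last difference set to zero (Neumann boundary), so constants map to zero
    and the l1 norm of the stack is the weighted 3D TV value.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected a 3rd-order volume")
    out = np.zeros((3,) + x.shape, dtype=float)
    for d, wd in enumerate(w.as_tuple()):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[d] = slice(0, x.shape[d] - 1)
        sl_hi[d] = slice(1, x.shape[d])
        out[d][tuple(sl_lo)] = wd * (x[tuple(sl_hi)] - x[tuple(sl_lo)])
    return out


def tv_diff_adjoint(f: np.ndarray, w: TVWeights) -> np.ndarray:
    """Exact adjoint of :func:`tv_diff` (weighted negative divergence)."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 4 or f.shape[0] != 3:
        raise ValueError("expected a (3, W, H, D) stacked difference tensor")
    shape = f.shape[1:]
    out = np.zeros(shape, dtype=float)
    for d, wd in enumerate(w.as_tuple()):
        g = f[d]
        # <G x, g> = sum_{i<n-1} (x[i+1]-x[i]) g[i]  =>  adj[j] = g[j-1] - g[j]
        # with g[-1] absent and g[n-1] never used.
        sl_int = [slice(None)] * 3
        sl_int[d] = slice(0, shape[d] - 1)
        contrib = np.zeros(shape, dtype=float)
        contrib[tuple(sl_int)] -= g[tuple(sl_int)]
        sl_to = [slice(None)] * 3
        sl_to[d] = slice(1, shape[d])
        contrib[tuple(sl_to)] += g[tuple(sl_int)]
        out += wd * contrib
    return out


def tv_value(x: np.ndarray, w: TVWeights) -> float:
    """Weighted anisotropic 3D total variation: l1 norm of :func:`tv_diff`."""
    return float(np.abs(tv_diff(x, w)).sum())
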