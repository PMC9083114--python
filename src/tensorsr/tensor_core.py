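"""Multilinear algebra primitives.

Conventions
-----------
The mode-``n`` unfolding of an N-way tensor ``T`` of shape ``(I_1, ..., I_N)``
is the ``I_n x prod(I_m, m != n)`` matrix whose column index enumerates the
remaining modes with the *earlier* modes varying fastest (column-major /
Fortran enumeration of ``(i_1, ..., i_{n-1}, i_{n+1}, ..., i_N)``).  In
1-based index notation the column of element ``(i_1, ..., i_N)`` is

    j = 1 + sum_{k != n} (i_k - 1) * J_k,   J_k = prod_{m < k, m != n} I_m.

All modes are 0-based in code.  This is the standard Kolda–Bader convention
and every routine in the package (Tucker reconstruction, Kronecker-vectorised
solves) relies on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TuckerFactors",
    "unfold",
    "fold",
    "mode_n_product",
    "multi_mode_product",
    "tucker_reconstruct",
    "hosvd_init",
    "inner",
    "frob",
]


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` matricization of ``tensor``.

    Rows index mode ``mode``; columns enumerate the remaining modes in
    column-major order (see module docstring).
    """
    tensor = np.asarray(tensor)
    if not 0 <= mode < tensor.ndim:
        raise ValueError(f"mode {mode} out of range for ndim {tensor.ndim}")
    return np.reshape(np.moveaxis(tensor, mode, 0), (tensor.shape[mode], -1), order="F")


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold`: rebuild the tensor of extents ``shape``."""
    shape = tuple(int(s) for s in shape)
    if not 0 <= mode < len(shape):
        raise ValueError(f"mode {mode} out of range for shape {shape}")
    matrix = np.asarray(matrix)
    lead = (shape[mode],) + tuple(s for i, s in enumerate(shape) if i != mode)
    if matrix.shape != (lead[0], int(np.prod(lead[1:], dtype=np.int64))):
        raise ValueError(f"matrix shape {matrix.shape} inconsistent with {shape} at mode {mode}")
    return np.moveaxis(np.reshape(matrix, lead, order="F"), 0, mode)


def mode_n_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` product ``tensor x_mode matrix``.

    Satisfies ``unfold(result, mode) == matrix @ unfold(tensor, mode)``.
    """
    tensor = np.asarray(tensor)
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != tensor.shape[mode]:
        raise ValueError(
            f"matrix {matrix.shape} incompatible with mode-{mode} extent {tensor.shape[mode]}"
        )
    moved = np.moveaxis(tensor, mode, -1)
    out = moved @ matrix.T
    return np.moveaxis(out, -1, mode)


def multi_mode_product(
    tensor: np.ndarray,
    matrices: list[np.ndarray | None],
    transpose: bool = False,
) -> np.ndarray:
    """Apply one matrix per mode (entries may be ``None`` to skip a mode)."""
    out = np.asarray(tensor)
    for mode, mat in enumerate(matrices):
        if mat is None:
            continue
        out = mode_n_product(out, mat.T if transpose else mat, mode)
    return out


def inner(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean inner product of two same-shaped tensors."""
    return float(np.vdot(np.asarray(a), np.asarray(b)))


def frob(a: np.ndarray) -> float:
    """Frobenius norm, equal for the tensor and any of its unfoldings."""
    return float(np.linalg.norm(np.asarray(a).ravel()))


@dataclass
class TuckerFactors:
    """Core tensor plus one factor matrix per mode.

    ``factors[n]`` has shape ``(I_n, S_n)`` where ``S_n = core.shape[n]``.
    """

    core: np.ndarray
    factors: list[np.ndarray] = field(default_factory=list)

    @property
    def ranks(self) -> tuple[int, ...]:
        return tuple(self.core.shape)

    def validate(self) -> None:
        if len(self.factors) != self.core.ndim:
            raise ValueError("one factor per core mode required")
        for n, u in enumerate(self.factors):
            if u.ndim != 2 or u.shape[1] != self.core.shape[n]:
                raise ValueError(
                    f"factor {n} shape {u.shape} inconsistent with core extent "
                    f"{self.core.shape[n]}"
                )


def tucker_reconstruct(f: TuckerFactors) -> np.ndarray:
    """Dense tensor ``core x_1 U1 x_2 ... x_N UN``."""
    f.validate()
    return multi_mode_product(f.core, list(f.factors))


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Flip singular-vector columns so the largest-magnitude entry is positive.

    SVD is sign-ambiguous per column; pinning the sign makes every downstream
    run reproducible bit-for-bit.
    """
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


def hosvd_init(tensor: np.ndarray, ranks: tuple[int, ...]) -> TuckerFactors:
    """Truncated higher-order SVD.

    Factor ``n`` holds the top ``ranks[n]`` left singular vectors of the
    mode-``n`` unfolding (orthonormal columns, sign-pinned); the core is the
    projection of ``tensor`` onto those bases.  Exact when the input has
    multilinear rank elementwise <= ``ranks``.
    """
    tensor = np.asarray(tensor)
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != tensor.ndim:
        raise ValueError("one rank per mode required")
    factors = []
    for n, r in enumerate(ranks):
        if not 1 <= r <= tensor.shape[n]:
            raise ValueError(f"rank {r} invalid for mode-{n} extent {tensor.shape[n]}")
        u, _, _ = np.linalg.svd(unfold(tensor, n), full_matrices=False)
        factors.append(_fix_signs(u[:, :r]))
    core = multi_mode_product(tensor, factors, transpose=True)
    return TuckerFactors(core=core, factors=factors)
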