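"""ADMM solver for single-volume 3D super-resolution with a nonlocal
patch-group Tucker prior (MCP-penalized factors), weighted 3D total
variation, and a Gaussian-blur + decimation observation model.

Model
-----
Given the low-resolution observation ``Y = D S X + eps``, the high-resolution
volume ``X`` is estimated by minimizing

    ||D S X - Y||_F^2 + lam_tv * TV_w(X)
      + lam1 * sum_{k,n} ||U_k^(n)||_{P_lam}
      + lam2 * sum_k ||G_k||_F^2
    s.t.  P_X^k = G_k x_1 U_k^(1) ... x_4 U_k^(4)   for every patch group k,

where ``P_X^k`` stacks the k-th key patch with its nearest nonlocal
neighbours into a 4th-order tensor, ``||.||_{P_lam}`` is the folded-concave
(MCP) spectral penalty, and ``TV_w`` is the weighted anisotropic 3D TV.

The objective is split with auxiliaries ``M`` (volume copy carrying the
nonlocal constraint), ``F`` (TV differences) and ``V_k^(n)`` (factor
copies), and solved by scaled-ADMM: six closed-form/CG primal updates per
sweep followed by dual ascent and a geometric penalty continuation.  All
per-group linear algebra is batched across groups; groups share one global
Tucker rank tuple (the elementwise maximum of per-group energy ranks), which
keeps every update a single batched LAPACK call.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .nonlocal_patches import PatchGrid, extract_patches, match_patches
from .operators import (
    DegradationSpec,
    TVWeights,
    blur_downsample,
    blur_downsample_adjoint,
    tv_diff,
    tv_diff_adjoint,
)
from .proximal import MCPParams, mcp_derivative, mcp_penalty, soft_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "SolverState",
    "init_state",
    "update_X",
    "update_F",
    "update_U",
    "update_V",
    "update_G",
    "update_M",
    "update_multipliers",
    "augmented_lagrangian",
    "primal_residuals",
    "superresolve",
    "upsample_initial",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SolverConfig:
    """All model and algorithm parameters.

    Regularization weights ``lam_tv``, ``lam1``, ``lam2`` default to the
    reference setting (10, 5, 20) with ``d = 15`` similar patches, a 1-voxel
    Gaussian blur and factor-2 decimation.  The ADMM penalty weights
    ``w1..w4`` and their geometric growth are algorithmic (not model)
    parameters; see docs/methods.md for how the defaults were chosen.
    """

    # model weights
    lam_tv: float = 10.0
    lam1: float = 5.0
    lam2: float = 20.0
    mcp: MCPParams = field(default_factory=MCPParams)
    tv_weights: TVWeights = field(default_factory=TVWeights)
    # observation model
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    # patch grouping
    grid: PatchGrid = field(default_factory=PatchGrid)
    n_similar: int = 15
    search_radius: int = 40
    rematch_every: int = 0
    # Tucker ranks: explicit tuple, or per-mode energy fraction of the
    # initial unfolding spectra (shared across groups via elementwise max)
    ranks: tuple | None = None
    rank_energy: float = 0.99
    # spectral scale of the initial factor matrices (cores are scaled down
    # to compensate).  A scale above mcp.a * mcp.lam starts the factors in
    # the flat (unbiased) MCP region and makes the core ridge's effective
    # shrinkage w4*s^8/(w4*s^8 + 2*lam2) ~ 1, so the solver sits in the
    # scale regime the folded-concave model favours from the first sweep.
    # The default keeps the plain (orthonormal) HOSVD initialization.
    factor_scale: float = 1.0
    # ADMM penalties
    w1: float = 1.0
    w2: float = 3.0
    w3: float = 50.0
    w4: float = 1e5
    penalty_growth: float = 1.2
    w_max: float = 1e8
    # solver control
    mcp_mode: str = "lla"
    init: str = "trilinear"
    cg_tol: float = 1e-6
    cg_maxiter: int = 100
    outer_tol: float = 1e-4
    max_outer_iters: int = 50
    seed: int = 0
    # intensity scale the solver works on internally: volumes are mapped to
    # [0, working_range] on entry and back to the observed range on exit.
    # The default model weights assume a dynamic range well above 1 (on unit
    # range the TV term overwhelms the data term); see docs/methods.md.
    working_range: float = 25.0

    def __post_init__(self):
        if min(self.lam_tv, self.lam1, self.lam2) < 0:
            raise ValueError("regularization weights must be >= 0")
        if min(self.w1, self.w2, self.w3, self.w4) <= 0:
            raise ValueError("penalty weights w1..w4 must be > 0")
        if self.penalty_growth < 1:
            raise ValueError("penalty_growth must be >= 1")
        if not 0 < self.outer_tol < 1:
            raise ValueError("outer_tol must be in (0, 1)")
        if self.mcp_mode not in ("lla", "constant"):
            raise ValueError("mcp_mode must be 'lla' or 'constant'")
        if self.init not in ("trilinear", "nearest"):
            raise ValueError("init must be 'trilinear' or 'nearest'")
        if not 0 < self.rank_energy <= 1:
            raise ValueError("rank_energy must be in (0, 1]")
        if self.n_similar < 1:
            raise ValueError("n_similar must be >= 1")


# ---------------------------------------------------------------------------
# batched group algebra (group axis first)
# ---------------------------------------------------------------------------


def _bmode(t: np.ndarray, mats: np.ndarray, mode: int) -> np.ndarray:
    """Batched mode product: apply ``mats[k]`` to mode ``mode`` of ``t[k]``."""
    moved = np.moveaxis(t, mode + 1, -1)
    lead = moved.shape[:-1]
    out = moved.reshape(t.shape[0], -1, moved.shape[-1]) @ mats.transpose(0, 2, 1)
    return np.moveaxis(out.reshape(lead + (mats.shape[1],)), -1, mode + 1)


def _bmulti(t: np.ndarray, mats: list, transpose: bool = False, skip: int = -1) -> np.ndarray:
    out = t
    for n, m in enumerate(mats):
        if n == skip or m is None:
            continue
        out = _bmode(out, m.transpose(0, 2, 1) if transpose else m, n)
    return out


def _bunfold(t: np.ndarray, mode: int) -> np.ndarray:
    """Batched mode unfolding; columns follow the earlier-modes-fastest rule."""
    moved = np.moveaxis(t, mode + 1, 1)
    rev = (0, 1) + tuple(range(moved.ndim - 1, 1, -1))
    return moved.transpose(rev).reshape(t.shape[0], t.shape[mode + 1], -1)


def _fix_signs_batched(u: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(u), axis=1, keepdims=True)
    signs = np.sign(np.take_along_axis(u, idx, axis=1))
    signs[signs == 0] = 1.0
    return u * signs


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------


@dataclass
class SolverState:
    """All ADMM variables; per-group arrays are batched with the group axis first."""

    y: np.ndarray
    hr_shape: tuple
    x: np.ndarray
    m: np.ndarray
    f: np.ndarray
    w1_mult: np.ndarray
    w2_mult: np.ndarray
    # per-group variables: factors[n] has shape (K, I_n, r_n)
    u_factors: list = field(default_factory=list)
    v_factors: list = field(default_factory=list)
    w3_mult: list = field(default_factory=list)
    cores: np.ndarray | None = None
    p_m: np.ndarray | None = None
    w4_mult: np.ndarray | None = None
    sigma_u: list = field(default_factory=list)
    # grouping geometry
    member_coords: np.ndarray | None = None  # (K, d, 3)
    ranks: tuple = ()
    patch_shape: tuple = ()
    # penalties (mutated by continuation)
    w: np.ndarray | None = None  # (w1, w2, w3, w4)
    iteration: int = 0
    history: list = field(default_factory=list)
    # precomputed scatter/gather indexing
    _flat_idx: np.ndarray | None = None
    _coverage: np.ndarray | None = None

    @property
    def n_groups(self) -> int:
        return 0 if self.member_coords is None else self.member_coords.shape[0]


def upsample_initial(
    y: np.ndarray, hr_shape: tuple, method: str = "trilinear"
) -> np.ndarray:
    """Interpolate the LR observation onto the HR grid (solver start point).

    HR voxel ``i`` maps to LR coordinate ``i / factor`` (decimation keeps
    index 0), interpolated linearly ('trilinear') or by rounding ('nearest')
    with edge replication.
    """
    y = np.asarray(y, dtype=float)
    coords = np.meshgrid(
        *[np.arange(h) / (hs / ls) for h, ls, hs in zip(hr_shape, y.shape, hr_shape)],
        indexing="ij",
    )
    order = 1 if method == "trilinear" else 0
    return map_coordinates(y, np.stack(coords), order=order, mode="nearest")


def _setup_groups(state: SolverState, config: SolverConfig, volume: np.ndarray) -> None:
    """(Re)build patch groups on ``volume`` and initialize Tucker variables."""
    patches, coords = extract_patches(volume, config.grid)
    d = min(config.n_similar, len(coords))
    if d < config.n_similar:
        logger.info("only %d patches available; using d = %d", len(coords), d)
    groups = [
        match_patches(patches, coords, k, d, config.search_radius)
        for k in range(len(coords))
    ]
    member_coords = np.stack([g.member_coords for g in groups])  # (K, d, 3)
    state.member_coords = member_coords
    b = config.grid.patch_size
    band = config.grid.resolve_band(volume.shape[2])
    state.patch_shape = (b, b, band, d)

    # scatter/gather indexing into the flattened HR volume
    s0 = state.hr_shape[1] * state.hr_shape[2]
    s1 = state.hr_shape[2]
    rel = (
        np.arange(b)[:, None, None] * s0
        + np.arange(b)[None, :, None] * s1
        + np.arange(band)[None, None, :]
    ).ravel()
    base = (
        member_coords[..., 0] * s0 + member_coords[..., 1] * s1 + member_coords[..., 2]
    ).reshape(-1)
    state._flat_idx = (base[:, None] + rel[None, :]).astype(np.intp)
    nvox = int(np.prod(state.hr_shape))
    state._coverage = np.bincount(state._flat_idx.ravel(), minlength=nvox).astype(float)

    data = _gather_groups(state, volume)
    state.ranks = _select_ranks(data, config)
    u_factors, cores = _hosvd_batched(data, state.ranks)
    s = float(config.factor_scale)
    if s != 1.0:
        u_factors = [s * u for u in u_factors]
        cores = cores / s ** len(state.ranks)
    state.u_factors = u_factors
    state.v_factors = [u.copy() for u in u_factors]
    state.w3_mult = [np.zeros_like(u) for u in u_factors]
    state.cores = cores
    state.p_m = data.copy()
    state.w4_mult = np.zeros_like(data)
    state.sigma_u = [np.full((data.shape[0], r), s) for r in state.ranks]


def _gather_groups(state: SolverState, volume: np.ndarray) -> np.ndarray:
    """Extract the (K, b, b, B, d) stack of group patches from a volume."""
    b, _, band, d = state.patch_shape
    k = state.n_groups
    flat = np.asarray(volume, dtype=float).ravel()[state._flat_idx]
    return flat.reshape(k, d, b, b, band).transpose(0, 2, 3, 4, 1)


def _scatter_average(
    state: SolverState, data: np.ndarray, fallback: np.ndarray
) -> np.ndarray:
    """Aggregate group slabs into a volume, averaging overlaps."""
    k, b, _, band, d = data.shape
    weights = data.transpose(0, 4, 1, 2, 3).reshape(k * d, -1)
    nvox = int(np.prod(state.hr_shape))
    acc = np.bincount(state._flat_idx.ravel(), weights=weights.ravel(), minlength=nvox)
    out = np.asarray(fallback, dtype=float).ravel().copy()
    covered = state._coverage > 0
    out[covered] = acc[covered] / state._coverage[covered]
    return out.reshape(state.hr_shape)


def _select_ranks(data: np.ndarray, config: SolverConfig) -> tuple:
    """One shared rank tuple: per mode, the max over groups of the smallest
    rank holding >= rank_energy of squared singular-value energy."""
    if config.ranks is not None:
        return tuple(
            min(int(r), data.shape[n + 1]) for n, r in enumerate(config.ranks)
        )
    ranks = []
    for n in range(4):
        s = np.linalg.svd(_bunfold(data, n), compute_uv=False)  # (K, I_n)
        energy = np.cumsum(s**2, axis=1)
        total = energy[:, -1:]
        total[total == 0] = 1.0
        need = energy >= (config.rank_energy - 1e-12) * total
        r = int(np.max(np.argmax(need, axis=1))) + 1
        ranks.append(r)
    return tuple(ranks)


def _hosvd_batched(data: np.ndarray, ranks: tuple):
    factors = []
    for n, r in enumerate(ranks):
        u, _, _ = np.linalg.svd(_bunfold(data, n), full_matrices=False)
        factors.append(_fix_signs_batched(u[:, :, :r]))
    cores = _bmulti(data, factors, transpose=True)
    return factors, cores


def init_state(
    y: np.ndarray, config: SolverConfig, hr_shape: tuple | None = None
) -> SolverState:
    """Build the initial ADMM state from the LR observation.

    ``hr_shape`` defaults to ``lr_shape * down_factor`` per axis.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected a 3rd-order LR volume")
    if not np.all(np.isfinite(y)):
        raise ValueError("LR observation must be finite")
    if hr_shape is None:
        hr_shape = tuple(s * f for s, f in zip(y.shape, config.degradation.factors))
    hr_shape = tuple(int(s) for s in hr_shape)
    if config.degradation.lr_shape(hr_shape) != y.shape:
        raise ValueError(
            f"hr_shape {hr_shape} inconsistent with LR shape {y.shape} under "
            f"factors {config.degradation.factors}"
        )
    x0 = upsample_initial(y, hr_shape, config.init)
    state = SolverState(
        y=y,
        hr_shape=hr_shape,
        x=x0,
        m=x0.copy(),
        f=tv_diff(x0, config.tv_weights),
        w1_mult=np.zeros(hr_shape),
        w2_mult=np.zeros((3,) + hr_shape),
        w=np.array([config.w1, config.w2, config.w3, config.w4], dtype=float),
    )
    _setup_groups(state, config, x0)
    return state


# ---------------------------------------------------------------------------
# the six primal updates
# ---------------------------------------------------------------------------


def update_X(state: SolverState, config: SolverConfig) -> np.ndarray:
    """Data-fidelity update: solve the normal equations

        (2 (DS)^T DS + w1 I + w2 G_w^T G_w) X
            = 2 (DS)^T Y + w1 M - W1 + w2 G_w^T (F + W2 / w2)

    matrix-free by conjugate gradients (warm-started at the current X).
    """
    deg, tvw = config.degradation, config.tv_weights
    w1, w2 = state.w[0], state.w[1]

    def apply_op(v: np.ndarray) -> np.ndarray:
        out = 2.0 * blur_downsample_adjoint(blur_downsample(v, deg), deg, state.hr_shape)
        out += w1 * v
        out += w2 * tv_diff_adjoint(tv_diff(v, tvw), tvw)
        return out

    rhs = 2.0 * blur_downsample_adjoint(state.y, deg, state.hr_shape)
    rhs += w1 * state.m - state.w1_mult
    rhs += w2 * tv_diff_adjoint(state.f + state.w2_mult / w2, tvw)

    x = state.x.copy()
    r = rhs - apply_op(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    rhs_norm = max(np.linalg.norm(rhs), _EPS)
    for _ in range(config.cg_maxiter):
        if np.sqrt(rs) / rhs_norm <= config.cg_tol:
            break
        ap = apply_op(p)
        alpha = rs / max(np.vdot(p, ap).real, _EPS)
        x += alpha * p
        r -= alpha * ap
        rs_new = np.vdot(r, r).real
        p = r + (rs_new / max(rs, _EPS)) * p
        rs = rs_new
    else:
        rel = np.sqrt(rs) / rhs_norm
        if rel > config.cg_tol:
            raise RuntimeError(
                f"CG did not reach tol {config.cg_tol:g} in {config.cg_maxiter} "
                f"iterations (relative residual {rel:.3e})"
            )
    state.x = x
    return x


def update_F(state: SolverState, config: SolverConfig) -> np.ndarray:
    """TV-auxiliary prox: per component n,
    ``F_n = soft(G_w X - W2_n / w2, lam_tv * alpha_n / w2)``."""
    w2 = state.w[1]
    diff = tv_diff(state.x, config.tv_weights)
    target = diff - state.w2_mult / w2
    f = np.empty_like(target)
    for n, alpha in enumerate(config.tv_weights.alphas):
        f[n] = soft_threshold(target[n], config.lam_tv * alpha / w2)
    state.f = f
    return f


def update_U(state: SolverState, config: SolverConfig) -> list:
    """MCP-driven factor shrink, batched over groups.

    Each factor is the singular-value shrink of ``V - W3 / w3``, the prox
    target of the augmented term ``(w3/2) ||U - V + W3/w3||^2``; thresholds
    are ``lam1 * lam / w3`` (constant mode) or ``(lam1 / w3) * P'_lam`` at
    the previous iterate's singular values (local-linear-approximation mode,
    the default), which leaves singular values in the flat MCP region
    untouched.
    """
    w3 = state.w[2]
    new_factors = []
    for n in range(4):
        a = state.v_factors[n] - state.w3_mult[n] / w3
        u, s, vt = np.linalg.svd(a, full_matrices=False)
        if config.mcp_mode == "constant" or config.lam1 == 0:
            thresh = config.lam1 * config.mcp.lam / w3
            s_new = np.maximum(s - thresh, 0.0)
        else:
            weights = mcp_derivative(state.sigma_u[n][:, : s.shape[1]], config.mcp)
            s_new = np.maximum(s - (config.lam1 / w3) * weights, 0.0)
        new_factors.append(np.einsum("kir,kr,krj->kij", u, s_new, vt))
        state.sigma_u[n] = s_new
    state.u_factors = new_factors
    return new_factors


def update_V(state: SolverState, config: SolverConfig) -> list:
    """Factor-auxiliary update (exact minimizer of its quadratic subproblem):

        V^(n) (w3 I + w4 B B^T) = w3 (U^(n) + W3^(n)/w3) + w4 T_(n) B^T,

    with ``T = P_M + W4 / w4`` and ``B = G_(n) (kron of other modes' V)^T``.
    Modes are swept Gauss–Seidel style with the freshest factors.
    """
    w3, w4 = state.w[2], state.w[3]
    t = state.p_m + state.w4_mult / w4
    for n in range(4):
        v = state.v_factors
        grams = [vm.transpose(0, 2, 1) @ vm for vm in v]
        g_n = _bunfold(state.cores, n)  # (K, r_n, R_-n)
        # B B^T = G_(n) (kron of other grams) G_(n)^T, computed as mode
        # products so the Kronecker product is never materialized
        g_weighted = _bmulti(state.cores, grams, skip=n)
        bbt = _bunfold(g_weighted, n) @ g_n.transpose(0, 2, 1)
        s = _bmulti(t, v, transpose=True, skip=n)
        data_term = _bunfold(s, n) @ g_n.transpose(0, 2, 1)  # (K, I_n, r_n)
        rhs = w3 * (state.u_factors[n] + state.w3_mult[n] / w3) + w4 * data_term
        a = w3 * np.eye(bbt.shape[1])[None] + w4 * bbt
        try:
            sol = np.linalg.solve(a, rhs.transpose(0, 2, 1))
        except np.linalg.LinAlgError:
            logger.warning("singular normal matrix in V update; regularizing")
            a = a + 1e-12 * np.eye(a.shape[1])[None]
            sol = np.linalg.solve(a, rhs.transpose(0, 2, 1))
        state.v_factors[n] = sol.transpose(0, 2, 1)
    return state.v_factors


def update_G(state: SolverState, config: SolverConfig) -> np.ndarray:
    """Core update: exact ridge-regularized least squares,

        (w4 kron(Gram_4, ..., Gram_1) + 2 lam2 I) vec(G)
            = vec((w4 P_M + W4) x_n V^(n)T for all n),

    the stationarity condition of
    ``lam2 ||G||_F^2 + (w4/2) ||P_M - G x_n V... + W4/w4||_F^2``.

    The Kronecker-structured system is solved in the tensor eigenbasis of
    the per-mode factor Grams (eigendecompose each Gram, rotate the
    right-hand side, divide by ``w4 * prod(eigenvalues) + 2 lam2``, rotate
    back), so the full Kronecker matrix is never formed.
    """
    w4 = state.w[3]
    v = state.v_factors
    grams = [vm.transpose(0, 2, 1) @ vm for vm in v]
    eig = [np.linalg.eigh(g) for g in grams]
    qs = [q for _, q in eig]
    rhs_t = _bmulti(w4 * state.p_m + state.w4_mult, v, transpose=True)
    rot = _bmulti(rhs_t, qs, transpose=True)
    denom = np.einsum(
        "ka,kb,kc,kd->kabcd", eig[0][0], eig[1][0], eig[2][0], eig[3][0]
    )
    # rank-deficient Grams with lam2 = 0: the rotated rhs vanishes in null
    # directions, so flooring the denominator yields the min-norm solution
    rot /= np.maximum(w4 * denom + 2.0 * config.lam2, 1e-30)
    state.cores = _bmulti(rot, qs)
    return state.cores


def update_M(state: SolverState, config: SolverConfig) -> np.ndarray:
    """Nonlocal-auxiliary update: per group

        P_M = (w4 C + w1 P_X + W1_patches - W4) / (w4 + w1),

    with ``C`` the Tucker reconstruction from the factor copies V (the same
    reconstruction the constraint and the dual ascent use, so this is the
    exact minimizer of the augmented Lagrangian in P_M), then aggregate the
    updated groups into the volume M (coverage-count averaging; voxels
    outside every patch keep the current X value).
    """
    w1, w4 = state.w[0], state.w[3]
    c = _bmulti(state.cores, state.v_factors)
    p_x = _gather_groups(state, state.x)
    w1_g = _gather_groups(state, state.w1_mult)
    state.p_m = (w4 * c + w1 * p_x + w1_g - state.w4_mult) / (w4 + w1)
    state.m = _scatter_average(state, state.p_m, fallback=state.x)
    return state.m


def update_multipliers(state: SolverState, config: SolverConfig) -> None:
    """Scaled-ADMM dual ascent on all four constraints, then penalty growth."""
    w1, w2, w3, w4 = state.w
    state.w1_mult = state.w1_mult + w1 * (state.x - state.m)
    state.w2_mult = state.w2_mult + w2 * (state.f - tv_diff(state.x, config.tv_weights))
    for n in range(4):
        state.w3_mult[n] = state.w3_mult[n] + w3 * (
            state.u_factors[n] - state.v_factors[n]
        )
    recon = _bmulti(state.cores, state.v_factors)
    state.w4_mult = state.w4_mult + w4 * (state.p_m - recon)
    state.w = np.minimum(state.w * config.penalty_growth, config.w_max)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def _rel(a: float, *scales: float) -> float:
    return a / max(max(scales), _EPS)


def primal_residuals(state: SolverState, config: SolverConfig) -> dict:
    """Relative norms of the four ADMM constraint violations."""
    gx = tv_diff(state.x, config.tv_weights)
    r1 = _rel(
        np.linalg.norm(state.x - state.m),
        np.linalg.norm(state.x),
        np.linalg.norm(state.m),
    )
    r2 = _rel(
        np.linalg.norm(state.f - gx), np.linalg.norm(state.f), np.linalg.norm(gx), 1.0
    )
    du = np.sqrt(
        sum(
            float(np.sum((u - v) ** 2))
            for u, v in zip(state.u_factors, state.v_factors)
        )
    )
    nu = np.sqrt(sum(float(np.sum(u**2)) for u in state.u_factors))
    nv = np.sqrt(sum(float(np.sum(v**2)) for v in state.v_factors))
    r3 = _rel(du, nu, nv)
    recon = _bmulti(state.cores, state.v_factors)
    r4 = _rel(
        np.linalg.norm((state.p_m - recon).ravel()),
        np.linalg.norm(state.p_m.ravel()),
        np.linalg.norm(recon.ravel()),
    )
    return {"x_m": r1, "f_gx": r2, "u_v": r3, "pm_tucker": r4}


def augmented_lagrangian(state: SolverState, config: SolverConfig) -> float:
    """Value of the scaled augmented Lagrangian at the current state."""
    w1, w2, w3, w4 = state.w
    deg, tvw = config.degradation, config.tv_weights
    val = float(np.sum((blur_downsample(state.x, deg) - state.y) ** 2))
    val += 0.5 * w1 * float(np.sum((state.x - state.m + state.w1_mult / w1) ** 2))
    gx = tv_diff(state.x, tvw)
    for n, alpha in enumerate(tvw.alphas):
        val += config.lam_tv * alpha * float(np.abs(state.f[n]).sum())
    val += 0.5 * w2 * float(np.sum((state.f - gx + state.w2_mult / w2) ** 2))
    val += config.lam2 * float(np.sum(state.cores**2))
    for n in range(4):
        val += config.lam1 * float(np.sum(mcp_penalty(state.sigma_u[n], config.mcp)))
        val += 0.5 * w3 * float(
            np.sum(
                (state.u_factors[n] - state.v_factors[n] + state.w3_mult[n] / w3) ** 2
            )
        )
    recon = _bmulti(state.cores, state.v_factors)
    val += 0.5 * w4 * float(np.sum((state.p_m - recon + state.w4_mult / w4) ** 2))
    return val


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


@dataclass
class SuperResolveResult:
    x: np.ndarray
    diagnostics: dict


def superresolve(
    y: np.ndarray,
    config: SolverConfig | None = None,
    hr_shape: tuple | None = None,
) -> SuperResolveResult:
    """Reconstruct the HR volume from a single LR observation.

    Intensities are affinely normalized to [0, 1] internally (the default
    regularization weights assume unit range) and mapped back on return; the
    output is clipped to the observed intensity range.  The run is fully
    deterministic for a fixed configuration.
    """
    config = config or SolverConfig()
    y = np.asarray(y, dtype=float)
    vmin, vmax = float(y.min()), float(y.max())
    scale = (vmax - vmin) / config.working_range
    y_n = (y - vmin) / scale if scale > 0 else np.zeros_like(y)

    state = init_state(y_n, config, hr_shape)
    logger.info(
        "groups=%d patch_shape=%s ranks=%s", state.n_groups, state.patch_shape, state.ranks
    )
    t0 = time.perf_counter()
    for it in range(1, config.max_outer_iters + 1):
        x_prev = state.x.copy()
        update_X(state, config)
        update_F(state, config)
        update_U(state, config)
        update_V(state, config)
        update_G(state, config)
        update_M(state, config)
        res = primal_residuals(state, config)
        obj = augmented_lagrangian(state, config)
        update_multipliers(state, config)
        if (
            config.rematch_every > 0
            and it % config.rematch_every == 0
            and it < config.max_outer_iters
        ):
            _setup_groups(state, config, state.x)
        if not np.all(np.isfinite(state.x)):
            raise RuntimeError(f"non-finite iterate at iteration {it}")
        rel_change = _rel(np.linalg.norm(state.x - x_prev), np.linalg.norm(x_prev))
        state.iteration = it
        entry = {
            "iteration": it,
            "objective": obj,
            "rel_change": rel_change,
            "elapsed_s": time.perf_counter() - t0,
            **res,
        }
        state.history.append(entry)
        logger.info(
            "iter %3d  obj %.6e  d(x) %.3e  res %.2e/%.2e/%.2e/%.2e",
            it,
            obj,
            rel_change,
            res["x_m"],
            res["f_gx"],
            res["u_v"],
            res["pm_tucker"],
        )
        max_res = max(res.values())
        if rel_change <= config.outer_tol and max_res <= config.outer_tol:
            break

    x_out = np.clip(state.x, 0.0, config.working_range)
    x_out = x_out * scale + vmin if scale > 0 else np.full(state.hr_shape, vmin)
    diagnostics = {
        "iterations": state.iteration,
        "history": state.history,
        "ranks": state.ranks,
        "n_groups": state.n_groups,
        "residuals": state.history[-1] if state.history else {},
        "intensity_range": (vmin, vmax),
    }
    return SuperResolveResult(x=x_out, diagnostics=diagnostics)
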