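"""Closed-form ADMM updates against independent numerical oracles.

Each update is checked on small seeded instances either by stationarity of
its own subproblem objective (numerical gradient at the returned point) or
by comparing its objective value against random perturbations.
"""

import copy

import numpy as np
import pytest

from tensorsr import solver as sv
from tensorsr import tensor_core as tc
from tensorsr.operators import DegradationSpec, TVWeights, blur_downsample, tv_diff
from tensorsr.proximal import MCPParams, svt
from tensorsr.solver import SolverConfig, SolverState, init_state


def make_group_state(rng, n_groups=2, shape=(4, 4, 3, 5), ranks=(2, 2, 2, 2)):
    """Minimal state carrying only the per-group Tucker variables."""
    st = SolverState(
        y=None, hr_shape=(8, 8, 6), x=None, m=None, f=None,
        w1_mult=None, w2_mult=None,
    )
    st.ranks = ranks
    st.patch_shape = shape
    st.w = np.array([1.0, 1.0, 2.0, 1.5])
    st.u_factors = [rng.normal(size=(n_groups, i, r)) for i, r in zip(shape, ranks)]
    st.v_factors = [rng.normal(size=(n_groups, i, r)) for i, r in zip(shape, ranks)]
    st.w3_mult = [0.1 * rng.normal(size=(n_groups, i, r)) for i, r in zip(shape, ranks)]
    st.cores = rng.normal(size=(n_groups,) + ranks)
    st.p_m = rng.normal(size=(n_groups,) + shape)
    st.w4_mult = 0.1 * rng.normal(size=(n_groups,) + shape)
    st.sigma_u = [np.ones((n_groups, r)) for r in ranks]
    st.member_coords = np.zeros((n_groups, 1, 3), dtype=int)
    return st


def numerical_gradient(obj, x0, eps=1e-6):
    g = np.zeros_like(x0)
    for idx in np.ndindex(x0.shape):
        e = np.zeros_like(x0)
        e[idx] = eps
        g[idx] = (obj(x0 + e) - obj(x0 - e)) / (2 * eps)
    return g


@pytest.fixture
def group_cfg():
    return SolverConfig(lam1=0.3, lam2=0.7, w3=2.0, w4=1.5)


class TestUpdateX:
    def _volume_state(self, rng, cfg, shape=(8, 8, 6)):
        y = rng.uniform(size=cfg.degradation.lr_shape(shape))
        st = SolverState(
            y=y, hr_shape=shape,
            x=rng.uniform(size=shape),
            m=rng.uniform(size=shape),
            f=0.1 * rng.normal(size=(3,) + shape),
            w1_mult=0.1 * rng.normal(size=shape),
            w2_mult=0.1 * rng.normal(size=(3,) + shape),
            w=np.array([0.5, 0.8, 1.0, 1.0]),
        )
        return st

    def test_identity_degradation_closed_form(self, rng):
        # D = S = identity, w2 = 0-like: X = (2Y + w1 M - W1) / (2 + w1)
        cfg = SolverConfig(
            degradation=DegradationSpec(blur_sigma=0.0, down_factor=1),
            w2=1e-12, cg_tol=1e-10, cg_maxiter=500,
        )
        shape = (6, 6, 4)
        st = SolverState(
            y=rng.uniform(size=shape), hr_shape=shape,
            x=np.zeros(shape), m=rng.uniform(size=shape),
            f=np.zeros((3,) + shape),
            w1_mult=0.1 * rng.normal(size=shape),
            w2_mult=np.zeros((3,) + shape),
            w=np.array([0.7, 1e-12, 1.0, 1.0]),
        )
        x = sv.update_X(st, cfg)
        expected = (2 * st.y + 0.7 * st.m - st.w1_mult) / (2 + 0.7)
        np.testing.assert_allclose(x, expected, atol=1e-8)

    def test_stationarity_of_quadratic_objective(self, rng):
        cfg = SolverConfig(cg_tol=1e-8, cg_maxiter=300)
        st = self._volume_state(rng, cfg)
        x = sv.update_X(st, cfg)
        deg, tvw = cfg.degradation, cfg.tv_weights
        w1, w2 = st.w[0], st.w[1]
        # gradient of the quadratic in Eq-form: A x - rhs
        gx = (
            2 * sv.blur_downsample_adjoint(blur_downsample(x, deg), deg, st.hr_shape)
            + w1 * x
            + w2 * sv.tv_diff_adjoint(tv_diff(x, tvw), tvw)
        )
        rhs = (
            2 * sv.blur_downsample_adjoint(st.y, deg, st.hr_shape)
            + w1 * st.m - st.w1_mult
            + w2 * sv.tv_diff_adjoint(st.f + st.w2_mult / w2, tvw)
        )
        assert np.linalg.norm(gx - rhs) <= 1e-6 * np.linalg.norm(rhs)

    def test_all_zero_inputs_give_zero(self):
        cfg = SolverConfig()
        shape = (6, 6, 4)
        st = SolverState(
            y=np.zeros(cfg.degradation.lr_shape(shape)), hr_shape=shape,
            x=np.zeros(shape), m=np.zeros(shape), f=np.zeros((3,) + shape),
            w1_mult=np.zeros(shape), w2_mult=np.zeros((3,) + shape),
            w=np.array([1.0, 1.0, 1.0, 1.0]),
        )
        assert not sv.update_X(st, cfg).any()

    def test_cg_failure_raises(self, rng):
        cfg = SolverConfig(cg_tol=1e-14, cg_maxiter=1)
        st = self._volume_state(rng, cfg)
        with pytest.raises(RuntimeError, match="CG"):
            sv.update_X(st, cfg)


class TestUpdateF:
    def _state(self, rng, cfg, shape=(6, 6, 4)):
        return SolverState(
            y=None, hr_shape=shape, x=rng.uniform(size=shape), m=None,
            f=np.zeros((3,) + shape),
            w1_mult=None, w2_mult=0.1 * rng.normal(size=(3,) + shape),
            w=np.array([1.0, 0.8, 1.0, 1.0]),
        )

    def test_zero_inputs(self):
        cfg = SolverConfig()
        shape = (5, 5, 4)
        st = SolverState(
            y=None, hr_shape=shape, x=np.zeros(shape), m=None,
            f=np.zeros((3,) + shape), w1_mult=None,
            w2_mult=np.zeros((3,) + shape), w=np.array([1.0, 1.0, 1.0, 1.0]),
        )
        assert not sv.update_F(st, cfg).any()

    def test_zero_lam_tv_is_exact_target(self, rng):
        cfg = SolverConfig(lam_tv=0.0)
        st = self._state(rng, cfg)
        f = sv.update_F(st, cfg)
        target = tv_diff(st.x, cfg.tv_weights) - st.w2_mult / st.w[1]
        np.testing.assert_allclose(f, target, atol=1e-12)

    def test_prox_beats_perturbations(self, rng):
        cfg = SolverConfig(lam_tv=2.0)
        st = self._state(rng, cfg)
        f = sv.update_F(st, cfg)
        gx = tv_diff(st.x, cfg.tv_weights)
        w2 = st.w[1]

        def objective(fc):
            val = 0.5 * w2 * np.sum((fc - gx + st.w2_mult / w2) ** 2)
            for n, alpha in enumerate(cfg.tv_weights.alphas):
                val += cfg.lam_tv * alpha * np.abs(fc[n]).sum()
            return val

        base = objective(f)
        assert base <= objective(gx) + 1e-9
        for _ in range(50):
            assert base <= objective(f + 0.01 * rng.normal(size=f.shape)) + 1e-9


class TestUpdateU:
    def test_zero_target_gives_zero(self, rng, group_cfg):
        st = make_group_state(rng)
        for n in range(4):
            st.v_factors[n][:] = 0.0
            st.w3_mult[n][:] = 0.0
        u = sv.update_U(st, group_cfg)
        assert all(not f.any() for f in u)

    def test_zero_lam1_passes_target_through(self, rng):
        cfg = SolverConfig(lam1=0.0, w3=2.0)
        st = make_group_state(rng)
        u = sv.update_U(st, cfg)
        for n in range(4):
            target = st.v_factors[n] - st.w3_mult[n] / st.w[2]
            np.testing.assert_allclose(u[n], target, atol=1e-10)

    def test_constant_mode_is_svt_per_factor(self, rng):
        cfg = SolverConfig(lam1=0.3, w3=2.0, mcp_mode="constant")
        st = make_group_state(rng)
        v0 = [f.copy() for f in st.v_factors]
        w30 = [m.copy() for m in st.w3_mult]
        u = sv.update_U(st, cfg)
        tau = cfg.lam1 * cfg.mcp.lam / st.w[2]
        for n in range(4):
            for k in range(v0[n].shape[0]):
                np.testing.assert_allclose(
                    u[n][k], svt(v0[n][k] - w30[n][k] / st.w[2], tau), atol=1e-10
                )

    def test_lla_majorized_objective_beats_perturbations(self, rng):
        cfg = SolverConfig(lam1=0.5, w3=2.0, mcp_mode="lla")
        st = make_group_state(rng)
        sigma_prev = [s.copy() for s in st.sigma_u]
        v0 = [f.copy() for f in st.v_factors]
        w30 = [m.copy() for m in st.w3_mult]
        u = sv.update_U(st, cfg)
        from tensorsr.proximal import mcp_derivative

        n, k = 1, 0
        weights = mcp_derivative(sigma_prev[n][k], cfg.mcp)
        target = v0[n][k] - w30[n][k] / st.w[2]

        def majorized(mat):
            s = np.linalg.svd(mat, compute_uv=False)
            return cfg.lam1 * np.sum(weights[: len(s)] * s) + 0.5 * st.w[2] * np.sum(
                (mat - target) ** 2
            )

        base = majorized(u[n][k])
        for _ in range(100):
            assert base <= majorized(u[n][k] + 0.01 * rng.normal(size=u[n][k].shape)) + 1e-9


class TestUpdateV:
    def test_w4_zero_limit_is_target(self, rng, group_cfg):
        # with the coupling and its multiplier off, only the first quadratic
        # remains and V matches its unconstrained minimizer
        st = make_group_state(rng)
        st.w[3] = 1e-10
        st.w4_mult[:] = 0.0
        v = sv.update_V(st, group_cfg)
        for n in range(4):
            target = st.u_factors[n] + st.w3_mult[n] / st.w[2]
            np.testing.assert_allclose(v[n], target, atol=1e-6)

    def test_stationarity_gauss_seidel(self, rng, group_cfg):
        st = make_group_state(rng)
        before = [f.copy() for f in st.v_factors]
        sv.update_V(st, group_cfg)
        w3, w4 = st.w[2], st.w[3]
        for n in range(4):
            for k in range(st.n_groups):
                # context: modes < n already updated, modes > n at old values
                ctx = [
                    (st.v_factors[m][k] if m < n else before[m][k]) for m in range(4)
                ]
                ctx[n] = st.v_factors[n][k]
                t = st.p_m[k] + st.w4_mult[k] / w4
                u, w3m = st.u_factors[n][k], st.w3_mult[n][k]

                def obj(vn):
                    facs = list(ctx)
                    facs[n] = vn
                    rec = tc.tucker_reconstruct(
                        tc.TuckerFactors(core=st.cores[k], factors=facs)
                    )
                    return 0.5 * w3 * np.sum((u - vn + w3m / w3) ** 2) + 0.5 * w4 * np.sum(
                        (t - rec) ** 2
                    )

                g = numerical_gradient(obj, ctx[n])
                assert np.linalg.norm(g) <= 1e-5 * max(np.linalg.norm(ctx[n]), 1.0)

    def test_zero_state_stays_zero(self, group_cfg):
        rng = np.random.default_rng(0)
        st = make_group_state(rng)
        for n in range(4):
            st.u_factors[n][:] = 0
            st.v_factors[n][:] = 0
            st.w3_mult[n][:] = 0
        st.cores[:] = 0
        st.p_m[:] = 0
        st.w4_mult[:] = 0
        v = sv.update_V(st, group_cfg)
        assert all(not f.any() for f in v)


class TestUpdateG:
    def test_orthonormal_factors_lam2_zero_is_projection(self, rng):
        cfg = SolverConfig(lam2=0.0, w4=1.5)
        st = make_group_state(rng)
        for n in range(4):
            for k in range(st.n_groups):
                q, _ = np.linalg.qr(st.v_factors[n][k])
                st.v_factors[n][k] = q
        st.w4_mult[:] = 0.0
        g = sv.update_G(st, cfg)
        for k in range(st.n_groups):
            expected = tc.multi_mode_product(
                st.p_m[k], [st.v_factors[n][k] for n in range(4)], transpose=True
            )
            np.testing.assert_allclose(g[k], expected, atol=1e-8)

    def test_stationarity(self, rng, group_cfg):
        st = make_group_state(rng)
        sv.update_G(st, group_cfg)
        w4 = st.w[3]
        for k in range(st.n_groups):
            facs = [st.v_factors[n][k] for n in range(4)]
            t = st.p_m[k] + st.w4_mult[k] / w4

            def obj(core):
                rec = tc.tucker_reconstruct(tc.TuckerFactors(core=core, factors=facs))
                return group_cfg.lam2 * np.sum(core**2) + 0.5 * w4 * np.sum((t - rec) ** 2)

            g = numerical_gradient(obj, st.cores[k])
            assert np.linalg.norm(g) <= 1e-5 * max(np.linalg.norm(st.cores[k]), 1.0)

    def test_huge_ridge_annihilates_core(self, rng):
        cfg = SolverConfig(lam2=1e12, w4=1.5)
        st = make_group_state(rng)
        g = sv.update_G(st, cfg)
        assert np.linalg.norm(g) <= 1e-6


class TestUpdateM:
    def _hr_state(self, rng, cfg, shape=(12, 12, 8)):
        y = rng.uniform(size=cfg.degradation.lr_shape(shape))
        st = init_state(y, cfg, shape)
        st.x = rng.uniform(size=shape)
        st.w1_mult = 0.1 * rng.normal(size=shape)
        return st

    def test_consistent_reconstruction_fixed_point(self, rng):
        # C = P_X and all multipliers zero: P_M = P_X, M = X on covered voxels
        cfg = SolverConfig(
            grid=sv.PatchGrid(patch_size=4, stride=4, band_extent=4),
            n_similar=1, ranks=(4, 4, 4, 1),
        )
        st = self._hr_state(rng, cfg)
        p_x = sv._gather_groups(st, st.x)
        facs, cores = sv._hosvd_batched(p_x, (4, 4, 4, 1))
        st.v_factors = facs
        st.cores = cores
        st.w1_mult[:] = 0.0
        st.w4_mult[:] = 0.0
        m = sv.update_M(st, cfg)
        np.testing.assert_allclose(m, st.x, atol=1e-8)

    def test_w4_zero_limit(self, rng):
        cfg = SolverConfig(
            grid=sv.PatchGrid(patch_size=4, stride=4, band_extent=4), n_similar=2
        )
        st = self._hr_state(rng, cfg)
        st.w = np.array([0.7, 1.0, 1.0, 1e-12])
        sv.update_M(st, cfg)
        expected = sv._gather_groups(st, st.x) + sv._gather_groups(
            st, st.w1_mult
        ) / 0.7
        np.testing.assert_allclose(st.p_m, expected, atol=1e-6)

    def test_closed_form_beats_endpoints(self, rng):
        cfg = SolverConfig(
            grid=sv.PatchGrid(patch_size=4, stride=4, band_extent=4), n_similar=2
        )
        st = self._hr_state(rng, cfg)
        st.w4_mult = 0.1 * rng.normal(size=st.p_m.shape)
        w1, w4 = st.w[0], st.w[3]
        c = sv._bmulti(st.cores, st.v_factors)
        p_x = sv._gather_groups(st, st.x)
        w1g = sv._gather_groups(st, st.w1_mult)
        sv.update_M(st, cfg)

        def objective(p_m):
            return 0.5 * w1 * np.sum((p_x - p_m + w1g / w1) ** 2) + 0.5 * w4 * np.sum(
                (p_m - c + st.w4_mult / w4) ** 2
            )

        base = objective(st.p_m)
        assert base <= objective(c) + 1e-9
        assert base <= objective(p_x) + 1e-9
        for _ in range(100):
            assert base <= objective(st.p_m + 0.01 * rng.normal(size=c.shape)) + 1e-9


class TestMultipliers:
    def test_zero_residuals_leave_multipliers(self, rng):
        cfg = SolverConfig(
            grid=sv.PatchGrid(patch_size=4, stride=4, band_extent=4),
            n_similar=1, ranks=(4, 4, 4, 1), penalty_growth=1.0,
            lam_tv=0.0, lam1=0.0, lam2=0.0,
        )
        shape = (8, 8, 4)
        y = rng.uniform(size=cfg.degradation.lr_shape(shape))
        st = init_state(y, cfg, shape)
        st.m = st.x.copy()
        st.f = tv_diff(st.x, cfg.tv_weights)
        st.v_factors = [u.copy() for u in st.u_factors]
        st.p_m = sv._bmulti(st.cores, st.v_factors)
        w1_before = st.w1_mult.copy()
        sv.update_multipliers(st, cfg)
        np.testing.assert_allclose(st.w1_mult, w1_before, atol=1e-12)
        assert all(not w.any() for w in st.w3_mult)
        assert np.abs(st.w4_mult).max() < 1e-10

    def test_single_ascent_step_is_definitional(self, rng):
        cfg = SolverConfig(
            grid=sv.PatchGrid(patch_size=4, stride=4, band_extent=4),
            n_similar=1, penalty_growth=1.0,
        )
        shape = (8, 8, 4)
        y = rng.uniform(size=cfg.degradation.lr_shape(shape))
        st = init_state(y, cfg, shape)
        st.m = rng.uniform(size=shape)
        w1 = st.w[0]
        expected = st.w1_mult + w1 * (st.x - st.m)
        sv.update_multipliers(st, cfg)
        np.testing.assert_allclose(st.w1_mult, expected, atol=1e-12)

    def test_penalty_growth_capped(self, rng):
        cfg = SolverConfig(
            grid=sv.PatchGrid(patch_size=4, stride=4, band_extent=4),
            n_similar=1, penalty_growth=10.0, w_max=5.0, w1=1.0, w2=1.0,
            w3=1.0, w4=1.0,
        )
        shape = (8, 8, 4)
        st = init_state(rng.uniform(size=cfg.degradation.lr_shape(shape)), cfg, shape)
        sv.update_multipliers(st, cfg)
        assert (st.w <= 5.0 + 1e-12).all()
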