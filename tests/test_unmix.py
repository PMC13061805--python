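"""Unmixing solver: operators, proximal pieces, ADMM correctness."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize, nnls

from papunmix.io_imaging import ODImage, rgb_to_od
from papunmix.phantom import PhantomConfig, make_phantom
from papunmix.stain_matrix import StainMatrix, normalize_columns
from papunmix.unmix import (
    AbundanceMap,
    SolverConfig,
    apply_diff_h,
    apply_diff_h_adjoint,
    apply_diff_v,
    apply_diff_v_adjoint,
    build_weight_matrix,
    cd_pseudoinverse,
    forward_model,
    ms_pseudoinverse,
    objective_value,
    soft_threshold,
    solve_normal_equations,
    tv_value,
    unmix_admm,
    update_weights,
)


def _random_stain(rng, r=4):
    raw = rng.uniform(0.05, 1.0, size=(3, r))
    names = ("EY", "H", "LG", "OG")[:r]
    return normalize_columns(raw, dye_names=names)


def _od(values, h, w):
    return ODImage(values=np.asarray(values, dtype=float), height=h, width=w)


class TestForwardModel:
    def test_zero_abundance(self, bundled_A):
        X = AbundanceMap(values=np.zeros((4, 6)), height=2, width=3)
        assert np.all(forward_model(bundled_A, X).values == 0)

    def test_unit_hematoxylin_reproduces_column(self, bundled_A):
        values = np.zeros((4, 1))
        values[1, 0] = 1.0
        X = AbundanceMap(values=values, height=1, width=1)
        out = forward_model(bundled_A, X).values[:, 0]
        assert out == pytest.approx(bundled_A.column("H"))

    def test_matches_triple_loop(self, rng, bundled_A):
        X = AbundanceMap(values=rng.uniform(0, 2, (4, 6)), height=2, width=3)
        out = forward_model(bundled_A, X).values
        A = bundled_A.coefficients
        for i in range(3):
            for j in range(6):
                s = sum(A[i, k] * X.values[k, j] for k in range(4))
                assert out[i, j] == pytest.approx(s, rel=1e-12)


class TestPseudoinverses:
    def test_square_invertible_exact(self, rng):
        A = _random_stain(rng, r=3)
        X0 = rng.uniform(0, 2, size=(3, 8))
        Y = _od(A.coefficients @ X0, 2, 4)
        rec = cd_pseudoinverse(Y, A, clip=False)
        assert np.allclose(rec.values, X0, atol=1e-10)

    def test_minimum_norm_solution_for_four_dyes(self, bundled_A):
        # Y from a pure-EY pixel: the 3x4 pseudoinverse returns the
        # minimum-norm preimage, generally not the unit-EY vector.
        y = bundled_A.column("EY")[:, None]
        rec = cd_pseudoinverse(_od(y, 1, 1), bundled_A, clip=False)
        oracle = np.linalg.pinv(bundled_A.coefficients) @ y
        assert np.allclose(rec.values, oracle, atol=1e-12)
        assert not np.allclose(rec.values[:, 0], [1, 0, 0, 0], atol=1e-3)
        assert np.linalg.norm(rec.values) <= 1.0 + 1e-9

    def test_zero_od_gives_zero(self, bundled_A):
        rec = cd_pseudoinverse(_od(np.zeros((3, 4)), 2, 2), bundled_A)
        assert np.all(rec.values == 0)

    def test_clip_removes_negatives(self, bundled_A, rng):
        Y = _od(rng.uniform(0, 1, (3, 9)), 3, 3)
        assert np.all(cd_pseudoinverse(Y, bundled_A, clip=True).values >= 0)

    def test_ms_consistent_system_recovered_exactly(self, rng):
        raw = rng.uniform(0.05, 1.0, size=(14, 4))
        E = normalize_columns(raw, wavelengths_nm=np.linspace(440, 720, 14))
        X0 = rng.uniform(0, 2, size=(4, 6))
        rec = ms_pseudoinverse(E.coefficients @ X0, E, 2, 3)
        assert np.allclose(rec.values, X0, atol=1e-9)

    def test_ms_residual_orthogonal_to_column_space(self, rng):
        raw = rng.uniform(0.05, 1.0, size=(14, 4))
        E = normalize_columns(raw, wavelengths_nm=np.linspace(440, 720, 14))
        Y = rng.uniform(0, 1, size=(14, 5))
        rec = ms_pseudoinverse(Y, E, 1, 5)
        residual = Y - E.coefficients @ rec.values
        assert np.abs(E.coefficients.T @ residual).max() < 1e-9

    def test_ms_requires_more_bands_than_dyes(self, rng):
        raw = rng.uniform(0.05, 1.0, size=(4, 4))
        E = normalize_columns(raw, wavelengths_nm=np.array([440.0, 500, 560, 620]))
        with pytest.raises(ValueError, match="M > R"):
            ms_pseudoinverse(np.zeros((4, 4)), E, 2, 2)


class TestDifferenceOperators:
    def test_constant_maps_to_zero(self):
        X = np.full((2, 12), 3.3)
        assert np.all(apply_diff_h(X, 3, 4) == 0)
        assert np.all(apply_diff_v(X, 3, 4) == 0)

    def test_periodic_pair_on_1x2(self):
        X = np.array([[2.0, 5.0]])
        assert apply_diff_h(X, 1, 2)[0] == pytest.approx([-3.0, 3.0])

    def test_matches_neighbor_enumeration(self, rng):
        h, w = 4, 5
        X = rng.normal(size=(2, h * w))
        Dh = apply_diff_h(X, h, w)
        Dv = apply_diff_v(X, h, w)
        for c in range(2):
            grid = X[c].reshape(h, w)
            for i in range(h):
                for j in range(w):
                    assert Dh[c, i * w + j] == pytest.approx(
                        grid[i, j] - grid[i, (j + 1) % w]
                    )
                    assert Dv[c, i * w + j] == pytest.approx(
                        grid[i, j] - grid[(i + 1) % h, j]
                    )

    def test_adjoint_identity(self, rng):
        h, w = 5, 3
        X = rng.normal(size=(4, h * w))
        Y = rng.normal(size=(4, h * w))
        assert np.vdot(apply_diff_h(X, h, w), Y) == pytest.approx(
            np.vdot(X, apply_diff_h_adjoint(Y, h, w))
        )
        assert np.vdot(apply_diff_v(X, h, w), Y) == pytest.approx(
            np.vdot(X, apply_diff_v_adjoint(Y, h, w))
        )


class TestTV:
    def test_constant_zero(self):
        assert tv_value(np.full((4, 9), 2.0), 3, 3) == 0.0

    def test_vertical_stripes_2x2(self):
        # [[0, 1], [0, 1]]: four horizontal wrap pairs of gap 1, no vertical
        X = np.array([[0.0, 1.0, 0.0, 1.0]])
        assert tv_value(X, 2, 2) == pytest.approx(4.0)

    def test_positive_homogeneity(self, rng):
        X = rng.normal(size=(4, 20))
        assert tv_value(2.5 * X, 4, 5) == pytest.approx(2.5 * tv_value(X, 4, 5))


class TestProximalPieces:
    @pytest.mark.parametrize(
        "v,tau,expected", [(5.0, 2.0, 3.0), (-1.0, 2.0, 0.0), (-4.0, 1.0, -3.0)]
    )
    def test_soft_threshold_closed_form(self, v, tau, expected):
        assert soft_threshold(np.array([v]), tau)[0] == expected

    def test_soft_threshold_zero_tau_is_identity(self, rng):
        v = rng.normal(size=10)
        assert np.array_equal(soft_threshold(v, 0.0), v)

    def test_soft_threshold_elementwise_oracle(self, rng):
        v = rng.normal(size=(3, 7))
        tau = rng.uniform(0, 1, size=(3, 7))
        out = soft_threshold(v, tau)
        for idx in np.ndindex(v.shape):
            expected = np.sign(v[idx]) * max(abs(v[idx]) - tau[idx], 0.0)
            assert out[idx] == pytest.approx(expected)

    def test_soft_threshold_rejects_negative_tau(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)

    def test_weights_at_zero_abundance_are_one(self):
        assert np.all(update_weights(np.zeros(5)) == 1.0)

    def test_weights_closed_form_and_monotone(self):
        assert update_weights(np.array([math.log(2)]))[0] == pytest.approx(0.5)
        w = update_weights(np.array([0.0, 1.0, 10.0]))
        assert np.all(np.diff(w) < 0)
        assert np.all((w > 0) & (w <= 1))

    def test_weights_require_clipped_input(self):
        with pytest.raises(ValueError):
            update_weights(np.array([-0.1]))

    def test_weight_matrix_structure(self):
        W = build_weight_matrix(np.array([0.5, 1.0]))
        assert np.all(W[[0, 2, 3]] == 0)
        assert W[1] == pytest.approx([0.5, 1.0])

    def test_weight_matrix_penalty_arithmetic(self):
        W = build_weight_matrix(np.array([0.5]))
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        assert np.abs(W * X).sum() == pytest.approx(1.0)


class TestObjective:
    def test_zero_abundance(self, bundled_A, rng):
        Y = rng.uniform(0, 1, size=(3, 6))
        W = np.zeros((4, 6))
        val = objective_value(np.zeros((4, 6)), Y, bundled_A.coefficients, W, 0, 0, 2, 3)
        assert val == pytest.approx(0.5 * np.sum(Y**2))

    def test_exact_solution_no_penalty(self, bundled_A, rng):
        X = rng.uniform(0, 1, size=(4, 6))
        Y = bundled_A.coefficients @ X
        W = np.zeros((4, 6))
        assert objective_value(X, Y, bundled_A.coefficients, W, 0, 0, 2, 3) == pytest.approx(0)

    def test_negative_entry_is_infeasible(self, bundled_A):
        X = np.zeros((4, 4))
        X[0, 0] = -1e-9
        val = objective_value(X, np.zeros((3, 4)), bundled_A.coefficients,
                              np.zeros((4, 4)), 1, 1, 2, 2)
        assert math.isinf(val)

    def test_matches_term_by_term_brute_force(self, bundled_A, rng):
        h, w = 3, 4
        X = rng.uniform(0, 2, size=(4, 12))
        Y = rng.uniform(0, 1, size=(3, 12))
        weights = rng.uniform(0.1, 1.0, size=12)
        W = build_weight_matrix(weights)
        lam, lam_tv = 0.3, 0.7
        val = objective_value(X, Y, bundled_A.coefficients, W, lam, lam_tv, h, w)
        fit = 0.5 * np.sum((bundled_A.coefficients @ X - Y) ** 2)
        sparsity = lam * np.sum(weights * np.abs(X[1]))
        tv = lam_tv * tv_value(X, h, w)
        assert val == pytest.approx(fit + sparsity + tv, rel=1e-12)


class TestNormalEquationsSolve:
    def test_fft_equals_dense_direct_solve(self, rng):
        h = w = 6
        n = h * w
        r = 4
        A = _random_stain(rng).coefficients
        mu = 0.05
        rhs = rng.normal(size=(r, n))
        out = solve_normal_equations(rhs, A, mu, h, w)
        Dh = np.zeros((n, n))
        Dv = np.zeros((n, n))
        for i in range(n):
            e = np.zeros((1, n))
            e[0, i] = 1.0
            Dh[:, i] = apply_diff_h(e, h, w).ravel()
            Dv[:, i] = apply_diff_v(e, h, w).ravel()
        M = np.kron(A.T @ A, np.eye(n)) + mu * (
            2 * np.eye(r * n) + np.kron(np.eye(r), Dh.T @ Dh + Dv.T @ Dv)
        )
        oracle = np.linalg.solve(M, rhs.ravel()).reshape(r, n)
        assert np.abs(out - oracle).max() < 1e-8


def _unique_nnls_od(rng, A, h, w, margin=0.15):
    """Random OD whose per-pixel NNLS problem has a unique minimizer.

    Uniqueness requires the solution's zero set to block the null
    direction of the 3x4 stain matrix on both sides, with a margin so
    the valley is not nearly flat (see the acceptance suite for the
    full rationale).
    """
    from scipy.linalg import null_space

    nu = null_space(A.coefficients).ravel()
    cols = []
    while len(cols) < h * w:
        y = rng.uniform(0.0, 1.5, size=3)
        x, res = nnls(A.coefficients, y)
        if res < 1e-3:
            continue
        lo = any(x[j] < 1e-12 and nu[j] >= margin for j in range(4))
        hi = any(x[j] < 1e-12 and nu[j] <= -margin for j in range(4))
        if lo and hi:
            cols.append(y)
    return _od(np.array(cols).T, h, w)


class TestADMM:
    def test_zero_input_converges_immediately(self, bundled_A):
        res = unmix_admm(_od(np.zeros((3, 16)), 4, 4), bundled_A)
        assert np.all(res.abundance.values == 0)
        assert res.iterations <= 2

    def test_matches_per_pixel_nnls_without_regularization(self, rng):
        for _ in range(5):
            A = _random_stain(rng)
            Y = _unique_nnls_od(rng, A, 4, 4)
            cfg = SolverConfig(lambda_sparsity=0, lambda_tv=0, weight_mode="off",
                               max_iter=5000, tol=1e-12)
            res = unmix_admm(Y, A, cfg)
            oracle = np.stack(
                [nnls(A.coefficients, Y.values[:, j])[0] for j in range(16)], axis=1
            )
            assert np.abs(res.abundance.values - oracle).max() < 1e-4

    def test_output_exactly_nonnegative(self, rng, bundled_A):
        Y = _od(rng.uniform(0, 1.5, size=(3, 36)), 6, 6)
        res = unmix_admm(Y, bundled_A, SolverConfig(max_iter=50))
        assert np.all(res.abundance.values >= 0)

    def test_final_weights_self_consistent(self, rng, bundled_A):
        Y = _od(rng.uniform(0, 1.0, size=(3, 25)), 5, 5)
        res = unmix_admm(Y, bundled_A, SolverConfig(max_iter=200))
        expected = np.exp(-np.clip(res.abundance.row("H"), 0, None))
        assert np.allclose(res.final_weights, expected)
        assert np.all((res.final_weights > 0) & (res.final_weights <= 1))

    def test_tv_zero_decouples_to_per_pixel_weighted_l1(self, rng, bundled_A):
        # fixed unit weights, lambda_TV = 0: each pixel solves
        # min 0.5||Ax - y||^2 + lam * x_H  s.t. x >= 0
        A = bundled_A.coefficients
        lam = 0.05
        Y = _od(rng.uniform(0.1, 1.2, size=(3, 9)), 3, 3)
        cfg = SolverConfig(lambda_sparsity=lam, lambda_tv=0.0,
                           weight_mode="fixed_unit", max_iter=8000, tol=1e-12)
        res = unmix_admm(Y, bundled_A, cfg)
        for j in range(9):
            y = Y.values[:, j]

            def f(x):
                r = A @ x - y
                return 0.5 * r @ r + lam * x[1]

            def grad(x):
                return A.T @ (A @ x - y) + lam * np.eye(4)[1]

            best = min(
                (
                    minimize(f, x0, jac=grad, method="L-BFGS-B",
                             bounds=[(0, None)] * 4,
                             options={"ftol": 1e-16, "gtol": 1e-12})
                    for x0 in (np.zeros(4), np.full(4, 0.5))
                ),
                key=lambda r: r.fun,
            )
            assert np.abs(res.abundance.values[:, j] - best.x).max() < 1e-4

    def test_objective_beats_zero_and_cd_baseline(self, small_phantom):
        ph = small_phantom
        od = rgb_to_od(ph.clean_rgb, ph.clean_rgb.incident_light)
        cfg = SolverConfig()
        res = unmix_admm(od, ph.stain_matrix, cfg)
        W = build_weight_matrix(res.final_weights)
        args = (od.values, ph.stain_matrix.coefficients, W,
                cfg.lambda_sparsity, cfg.lambda_tv, od.height, od.width)
        obj = objective_value(res.abundance.values, *args)
        assert obj <= objective_value(np.zeros_like(res.abundance.values), *args)
        cd = cd_pseudoinverse(od, ph.stain_matrix, clip=True)
        assert obj <= objective_value(cd.values, *args)

    def test_residuals_small_at_termination(self, small_phantom):
        ph = small_phantom
        od = rgb_to_od(ph.clean_rgb, ph.clean_rgb.incident_light)
        res = unmix_admm(od, ph.stain_matrix, SolverConfig())
        bound = 1e-3 * math.sqrt(4 * od.n_pixels)
        assert res.primal_residuals[-1] < bound
        assert res.dual_residuals[-1] < bound

    def test_noiseless_phantom_recovery(self):
        ph = make_phantom(PhantomConfig(height=32, width=32, n_cells=3,
                                        h_bleed=0.0, seed=5))
        od = rgb_to_od(ph.clean_rgb, ph.clean_rgb.incident_light)
        cfg = SolverConfig(lambda_sparsity=1e-9, lambda_tv=1e-9,
                           max_iter=8000, tol=1e-12)
        res = unmix_admm(od, ph.stain_matrix, cfg)
        assert np.abs(res.abundance.values - ph.truth.values).max() < 1e-2

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(admm_penalty=0.0)
        with pytest.raises(ValueError):
            SolverConfig(weight_mode="bogus")

    def test_non_finite_input_rejected(self, bundled_A):
        values = np.zeros((3, 4))
        od = _od(values, 2, 2)
        od.values[0, 0] = np.nan  # bypass constructor check deliberately
        with pytest.raises(ValueError, match="finite"):
            unmix_admm(od, bundled_A)
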