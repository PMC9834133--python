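"""IAS solver: energy, variance update, priorconditioned CGLS, outer loop."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from iasmeeg import (
    DipoleField,
    IASConfig,
    NoiseModel,
    VarianceField,
    energy,
    ias_solve,
    ias_time_series,
    solve_Q,
    update_theta,
)
from iasmeeg.solver import cgls

from conftest import make_hyper, small_problem


def theta_part(theta, w2, theta_star, eta):
    """The Theta-dependent part of the Gibbs energy for one dipole."""
    return w2 / (2 * theta) - eta * np.log(theta) + theta / theta_star


class TestUpdateTheta:
    def test_zero_moment_hits_floor(self):
        _, prior, _, _, _, _ = small_problem(0, n=1)
        hyper = make_hyper([2.0], eta=0.01)
        th = update_theta(DipoleField(np.zeros((1, 3))), prior, hyper)
        assert th.theta[0] == pytest.approx(0.02, rel=1e-12)

    def test_eta_zero_closed_form_collapse(self):
        # with eta = 0 and ||q||^2_C = 2 theta*, the update returns theta*
        _, prior, _, _, _, _ = small_problem(1, n=1, delta=1.0)
        hyper = make_hyper([3.0], eta=0.0)
        q = np.zeros((1, 3))
        q[0, 0] = np.sqrt(6.0)  # ||q||^2_C = 6 = 2 * theta*
        th = update_theta(DipoleField(q), prior, hyper)
        assert th.theta[0] == pytest.approx(3.0, rel=1e-12)

    def test_matches_scalar_minimization_oracle(self):
        # 1-D numerical minimization of the theta-part of the energy
        _, prior, _, _, _, _ = small_problem(2, n=1, delta=1.0)
        hyper = make_hyper([1.0], eta=0.1)
        q = np.zeros((1, 3))
        q[0, 1] = np.sqrt(0.5)
        th = update_theta(DipoleField(q), prior, hyper)
        res = minimize_scalar(
            lambda t: theta_part(t, 0.5, 1.0, 0.1),
            bounds=(1e-8, 50.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert th.theta[0] == pytest.approx(res.x, rel=1e-8)
        assert th.theta[0] == pytest.approx(0.55249, rel=1e-4)

    def test_floor_eta_theta_star(self, rng):
        _, prior, _, _, _, hyper = small_problem(3, n=4)
        q = rng.standard_normal((4, 3))
        q[2] = 0.0
        th = update_theta(DipoleField(q), prior, hyper)
        floor = hyper.eta * hyper.theta_star
        assert np.all(th.theta >= floor - 1e-15)
        assert th.theta[2] == pytest.approx(floor[2], rel=1e-12)
        assert np.all(th.theta[[0, 1, 3]] > floor[[0, 1, 3]])

    def test_strict_minimizer_under_perturbation(self, rng):
        _, prior, _, _, _, hyper = small_problem(4, n=3)
        q = rng.standard_normal((3, 3))
        w2 = prior.mahalanobis_sq(q)
        th = update_theta(DipoleField(q), prior, hyper).theta
        for j in range(3):
            base = theta_part(th[j], w2[j], hyper.theta_star[j], hyper.eta)
            for fac in (0.99, 1.01):
                assert theta_part(
                    fac * th[j], w2[j], hyper.theta_star[j], hyper.eta
                ) > base


class TestEnergy:
    def test_zero_state_closed_form(self):
        _, prior, M, _, noise, _ = small_problem(5, n=3, m=6)
        hyper = make_hyper([0.5, 1.0, 2.0], eta=1.0)
        E = energy(
            DipoleField(np.zeros((3, 3))),
            VarianceField(hyper.theta_star.copy()),
            np.zeros(6),
            M,
            prior,
            hyper,
            noise,
        )
        expected = np.sum(1.0 - np.log(hyper.theta_star))
        assert E == pytest.approx(expected, rel=1e-12)

    def test_misfit_depends_only_on_residual(self, rng):
        _, prior, M, b, noise, hyper = small_problem(6)
        q = rng.standard_normal((4, 3))
        th = VarianceField(rng.uniform(0.5, 2.0, 4))
        dq = rng.standard_normal((4, 3))
        E1 = energy(DipoleField(q), th, b, M, prior, hyper, noise)
        E2 = energy(DipoleField(q + dq), th, b + M @ dq.reshape(-1), M, prior, hyper, noise)
        # same residual: the difference is exactly the prior-term change
        dprior = 0.5 * np.sum(
            (prior.mahalanobis_sq(q + dq) - prior.mahalanobis_sq(q)) / th.theta
        )
        assert E2 - E1 == pytest.approx(dprior, rel=1e-9)

    def test_decreases_under_theta_update(self, rng):
        for seed in range(100):
            _, prior, M, b, noise, hyper = small_problem(100 + seed)
            q = np.random.default_rng(seed).standard_normal((4, 3))
            th0 = VarianceField(np.random.default_rng(seed + 1).uniform(0.2, 3.0, 4))
            th1 = update_theta(DipoleField(q), prior, hyper)
            E0 = energy(DipoleField(q), th0, b, M, prior, hyper, noise)
            E1 = energy(DipoleField(q), th1, b, M, prior, hyper, noise)
            assert E1 <= E0 + 1e-12

    def test_nonpositive_theta_rejected(self):
        _, prior, M, b, noise, hyper = small_problem(7)
        with pytest.raises(ValueError):
            VarianceField(np.array([1.0, -1.0, 1.0, 1.0]))


class TestCGLS:
    def test_matches_dense_least_squares(self, rng):
        A = rng.standard_normal((10, 15))
        y = rng.standard_normal(10)
        w, it, res = cgls(A, y, max_it=500)
        w_ref = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(A @ w, A @ w_ref, atol=1e-6)

    def test_residuals_non_increasing(self, rng):
        A = rng.standard_normal((20, 12))
        y = rng.standard_normal(20)
        _, _, res = cgls(A, y, max_it=200)
        assert np.all(np.diff(res) <= 1e-12)

    def test_zero_rhs_zero_iterations(self, rng):
        A = rng.standard_normal((5, 8))
        w, it, _ = cgls(A, np.zeros(5), max_it=100, discrepancy=5.0)
        assert it == 0 and np.array_equal(w, np.zeros(8))

    def test_damped_matches_tikhonov(self, rng):
        A = rng.standard_normal((12, 8))
        y = rng.standard_normal(12)
        w, _, _ = cgls(A, y, max_it=500, damp=1.0)
        w_ref = np.linalg.solve(A.T @ A + np.eye(8), A.T @ y)
        assert np.allclose(w, w_ref, atol=1e-8)


class TestSolveQ:
    def test_zero_data_returns_zero(self):
        _, prior, M, _, noise, hyper = small_problem(8)
        Q, it = solve_Q(
            np.zeros(6), M, prior, VarianceField(hyper.theta_star), noise,
            IASConfig(),
        )
        assert it == 0 and np.all(Q.moments == 0)

    def test_noiseless_consistent_matches_pseudoinverse(self, rng):
        # priorconditioned minimum-norm oracle: Q = D_theta^T A^+ y
        _, prior, M, _, noise, hyper = small_problem(9, n=2, m=8)
        theta = rng.uniform(0.5, 2.0, 2)
        Q_true = rng.standard_normal((2, 3))
        b = M @ Q_true.reshape(-1)
        cfg = IASConfig(inner_stop="max-only", max_it=2000)
        Q, _ = solve_Q(b, M, prior, VarianceField(theta), noise, cfg)
        from iasmeeg.solver import _priorconditioned_matrix

        A = _priorconditioned_matrix(M, prior, theta, noise)
        y = noise.whiten(b)
        w = np.linalg.pinv(A) @ y
        wq = w.reshape(2, 3)
        Q_ref = np.einsum(
            "nji,nj->ni", np.sqrt(theta)[:, None, None] * prior.factor, wq
        )
        assert np.allclose(Q.moments, Q_ref, atol=1e-8)

    def test_scaling_equivariance(self, rng):
        # scaling Sigma by c^2 and b, M by c leaves Q unchanged
        _, prior, M, b, noise, hyper = small_problem(10, n=10, m=6)
        theta = rng.uniform(0.5, 2.0, 10)
        cfg = IASConfig(inner_stop="max-only", max_it=400)
        Q1, _ = solve_Q(b, M, prior, VarianceField(theta), noise, cfg)
        c = 3.7
        noise2 = NoiseModel.isotropic(c * noise.sigma, 6)
        Q2, _ = solve_Q(c * b, c * M, prior, VarianceField(theta), noise2, cfg)
        assert np.allclose(Q1.moments, Q2.moments, atol=1e-10)

    def test_dimension_and_finiteness_errors(self):
        _, prior, M, b, noise, hyper = small_problem(11)
        with pytest.raises(ValueError):
            solve_Q(b[:-1], M, prior, VarianceField(hyper.theta_star), noise, IASConfig())
        Mbad = M.copy()
        Mbad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            solve_Q(b, Mbad, prior, VarianceField(hyper.theta_star), noise, IASConfig())


class TestIASSolve:
    def test_zero_data_fixed_point(self):
        _, prior, M, _, noise, hyper = small_problem(12)
        Q, Th, diag, converged = ias_solve(np.zeros(6), M, prior, hyper, noise)
        assert np.all(Q.moments == 0)
        assert np.allclose(Th.theta, hyper.eta * hyper.theta_star, rtol=1e-12)
        assert len(diag) == 2 and converged
        assert diag[0][1] == pytest.approx(1 - hyper.eta)
        assert diag[1][1] == 0.0

    def test_energy_non_increasing_with_exact_inner_solves(self):
        cfg = IASConfig(
            tau=1e-10, n_outer=40, max_it=500,
            inner_stop="max-only", explicit_penalty=True,
        )
        for seed in range(50):
            _, prior, M, b, noise, hyper = small_problem(200 + seed)
            theta = hyper.theta_star.copy()
            E_prev = np.inf
            for _ in range(8):
                Q, _ = solve_Q(b, M, prior, VarianceField(theta), noise, cfg)
                theta = update_theta(Q, prior, hyper).theta
                E = energy(
                    DipoleField(Q.moments), VarianceField(theta), b, M, prior,
                    hyper, noise,
                )
                assert E <= E_prev + 1e-10
                E_prev = E

    def test_diagnostics_shapes_and_caps(self):
        _, prior, M, b, noise, hyper = small_problem(13)
        cfg = IASConfig(tau=1e-14, n_outer=7, max_it=9)
        Q, Th, diag, _ = ias_solve(b, M, prior, hyper, noise, cfg)
        assert len(diag) <= 7
        assert all(inner <= 9 for inner, _ in diag)

    def test_theta_init_respected(self):
        _, prior, M, b, noise, hyper = small_problem(14)
        init = np.full(4, 0.123)
        _, _, diag1, _ = ias_solve(b, M, prior, hyper, noise, theta_init=init)
        _, _, diag2, _ = ias_solve(b, M, prior, hyper, noise)
        assert diag1[0][1] != diag2[0][1]  # different starting variance


class TestTimeSeries:
    def test_single_slice_equals_ias_solve(self):
        _, prior, M, b, noise, hyper = small_problem(15)
        res = ias_time_series(b[:, None], M, prior, hyper, noise)
        Q, Th, diag, _ = ias_solve(b, M, prior, hyper, noise)
        assert np.array_equal(res.Q_hat[0], Q.moments)
        assert np.array_equal(res.theta_hat[0], Th.theta)

    def test_constant_data_warm_start_converges_fast(self):
        _, prior, M, b, noise, hyper = small_problem(16)
        B = np.tile(b[:, None], (1, 3))
        cfg = IASConfig(tau=0.01, n_outer=30, max_it=120)
        res = ias_time_series(B, M, prior, hyper, noise, cfg, warm_start=True)
        if res.converged[0]:
            # at the fixed point of slice 1, slice 2 re-converges immediately
            assert len(res.diagnostics[1]) <= 2

    def test_nonfinite_column_isolated(self):
        _, prior, M, b, noise, hyper = small_problem(17)
        B = np.tile(b[:, None], (1, 3))
        B[0, 1] = np.nan
        res = ias_time_series(B, M, prior, hyper, noise)
        assert 1 in res.errors
        assert np.all(np.isnan(res.Q_hat[1]))
        assert np.all(np.isfinite(res.Q_hat[0])) and np.all(np.isfinite(res.Q_hat[2]))

    def test_intensities_are_row_norms(self):
        _, prior, M, b, noise, hyper = small_problem(18)
        res = ias_time_series(b[:, None], M, prior, hyper, noise)
        assert np.allclose(
            res.intensities[0], np.linalg.norm(res.Q_hat[0], axis=1), atol=1e-12
        )
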