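"""Square-root cubature Kalman filter: cubature rules, factorization,
classical-Kalman equivalence and excitability-ratio recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epikf.ckf import (
    FilterConfig,
    FilterTrace,
    NoiseModel,
    SqrtFilterState,
    apply_constraint,
    cubature_points,
    discrete_dynamics,
    measurement_update,
    run_filter,
    summarize_iba,
    time_update,
    triangularize,
)
from epikf.model import ModelParameters, N_MODEL_STATES, model_derivatives, simulate


class TestCubaturePoints:
    def test_one_dimension(self):
        pts = cubature_points(1)
        assert sorted(pts.ravel()) == [-1.0, 1.0]

    def test_augmented_state_gives_24_points(self):
        assert cubature_points(12).shape == (12, 24)

    @pytest.mark.parametrize("n", [1, 2, 5, 12])
    def test_zero_mean_and_unit_second_moment(self, n):
        pts = cubature_points(n)
        m = pts.shape[1]
        assert np.allclose(pts.mean(axis=1), 0)
        assert np.allclose(pts @ pts.T / m, np.eye(n))

    def test_rejects_degenerate_dimension(self):
        with pytest.raises(ValueError):
            cubature_points(0)


class TestTriangularize:
    def test_identity_fixed_point(self):
        assert np.allclose(triangularize(np.eye(4)), np.eye(4))

    def test_lower_triangular_input_unchanged(self):
        L = np.array([[2.0, 0.0], [1.0, 3.0]])
        assert np.allclose(triangularize(L), L)

    def test_gram_preserved_for_rectangular_input(self, rng):
        M = rng.standard_normal((3, 7))
        S = triangularize(M)
        assert np.allclose(S @ S.T, M @ M.T, atol=1e-12)
        assert np.allclose(np.triu(S, 1), 0)
        assert np.all(np.diag(S) >= 0)

    def test_rejects_tall_matrix(self):
        with pytest.raises(ValueError):
            triangularize(np.ones((5, 3)))


class TestDiscreteDynamics:
    def test_gain_component_has_zero_drift(self):
        cfg = FilterConfig()
        x = np.r_[np.linspace(-1, 1, N_MODEL_STATES), 22.0]
        for _ in range(5):
            x = discrete_dynamics(x, 90.0, cfg)
        assert x[-1] == 22.0

    def test_euler_definition(self):
        cfg = FilterConfig(T=1e-7)
        x = np.r_[np.linspace(-0.5, 0.5, N_MODEL_STATES), 20.0]
        step = discrete_dynamics(x, 90.0, cfg)
        deriv = (step - x) / cfg.T
        expected = model_derivatives(x[:11], 90.0, cfg.model.with_gains(B=x[-1]))
        assert np.allclose(deriv[:11], expected, rtol=1e-6, atol=1e-6)
        assert deriv[-1] == 0.0

    def test_matches_independent_augmented_evaluation(self):
        # second implementation of the augmented Euler step, written from
        # the model equations with B replaced by the twelfth component
        cfg = FilterConfig()
        p = cfg.model
        x = np.array([0.1, 1.0, 0.5, 0.2, 0.4, 0, -1, 2, 0.3, 0, 0.05, 18.0])
        d = np.zeros(12)
        d[:11] = model_derivatives(x[:11], 90.0, p.with_gains(B=x[11]))
        expected = x + cfg.T * d
        assert np.allclose(discrete_dynamics(x, 90.0, cfg), expected, rtol=1e-12)


def _linear_system():
    F = np.array([[0.9, 0.1], [0.0, 0.95]])
    H = np.array([[1.0, 0.2]])
    Q = np.diag([0.02, 0.01])
    R = np.array([[0.1]])
    return F, H, Q, R


def _classical_kalman(F, H, Q, R, x0, P0, ys):
    x, P = x0.copy(), P0.copy()
    means, covs = [], []
    for y in ys:
        x = F @ x
        P = F @ P @ F.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + (K @ (y - H @ x)).ravel()
        P = P - K @ H @ P
        means.append(x.copy())
        covs.append(P.copy())
    return means, covs


class TestLinearEquivalence:
    def test_matches_classical_kalman_filter(self, rng):
        """On a linear-Gaussian system the cubature rule is exact, so the
        square-root filter must reproduce the textbook Kalman recursion."""
        F, H, Q, R = _linear_system()
        noise = NoiseModel(S_Q=np.linalg.cholesky(Q), S_R=np.linalg.cholesky(R))
        cfg = FilterConfig()  # only carries T; dynamics/observation injected
        ys = rng.standard_normal(500)
        x0 = np.zeros(2)
        P0 = np.eye(2)
        ref_means, ref_covs = _classical_kalman(F, H, Q, R, x0, P0, ys)
        state = SqrtFilterState(x_hat=x0.copy(), S=np.linalg.cholesky(P0))
        for k, y in enumerate(ys):
            pred = time_update(state, 0.0, cfg, noise, dynamics=lambda X: F @ X)
            state, _ = measurement_update(
                pred, y, cfg, noise, observation=lambda X: (H @ X).ravel(),
                constrain=False,
            )
            assert np.allclose(state.x_hat, ref_means[k], atol=1e-10)
            assert np.allclose(state.covariance, ref_covs[k], atol=1e-10)

    def test_degenerate_deterministic_prediction(self):
        F, H, Q, R = _linear_system()
        noise = NoiseModel(S_Q=np.zeros((2, 2)), S_R=np.linalg.cholesky(R))
        cfg = FilterConfig()
        state = SqrtFilterState(x_hat=np.array([1.0, -2.0]), S=np.zeros((2, 2)))
        pred = time_update(state, 0.0, cfg, noise, dynamics=lambda X: F @ X)
        assert np.allclose(pred.S, 0)
        assert np.allclose(pred.x_hat, F @ state.x_hat)

    def test_zero_innovation_keeps_predicted_mean(self, rng):
        F, H, Q, R = _linear_system()
        noise = NoiseModel(S_Q=np.linalg.cholesky(Q), S_R=np.linalg.cholesky(R))
        cfg = FilterConfig()
        state = SqrtFilterState(x_hat=rng.standard_normal(2), S=np.eye(2))
        pred = time_update(state, 0.0, cfg, noise, dynamics=lambda X: F @ X)
        y_pred = float((H @ pred.x_hat)[0])
        post, innov = measurement_update(
            pred, y_pred, cfg, noise, observation=lambda X: (H @ X).ravel(),
            constrain=False,
        )
        assert innov == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(post.x_hat, pred.x_hat, atol=1e-12)


def _plain_ckf_step(x, P, y, cfg, noise, u1):
    """Non-square-root cubature Kalman filter step (independent oracle).

    Uses the Cholesky factor of the full covariance, which coincides with
    the square-root filter's triangular factor up to sign convention.
    """
    from epikf.ckf import augmented_derivatives, measurement_function

    n = len(x)
    xi = cubature_points(n)
    m = xi.shape[1]
    Q = noise.S_Q @ noise.S_Q.T
    R = noise.S_R @ noise.S_R.T
    X = x[:, None] + np.linalg.cholesky(P) @ xi
    Xp = X + cfg.T * augmented_derivatives(X, u1, cfg.model)
    xp = Xp.mean(axis=1)
    dX = Xp - xp[:, None]
    Pp = dX @ dX.T / m + Q
    X2 = xp[:, None] + np.linalg.cholesky(Pp) @ xi
    Y = np.atleast_2d(measurement_function(X2, cfg))
    yp = Y.mean(axis=1)
    dY = Y - yp[:, None]
    dX2 = X2 - xp[:, None]
    Pyy = dY @ dY.T / m + R
    Pxy = dX2 @ dY.T / m
    K = Pxy @ np.linalg.inv(Pyy)
    x_new = xp + (K @ (np.atleast_1d(y) - yp)).ravel()
    P_new = Pp - K @ Pyy @ K.T
    return x_new, P_new


class TestSquareRootConsistency:
    def test_covariance_matches_plain_ckf(self, base_params):
        """50 steps on simulated data: S S^T must track the full-covariance
        filter to 1e-9 relative Frobenius norm."""
        z, _ = simulate(base_params, 50 / 480, 480.0, seed=21)
        cfg = FilterConfig(measurement="z")
        noise = cfg.noise
        state = cfg.initial_state()
        x_ref, P_ref = state.x_hat.copy(), state.covariance
        u1 = cfg.model.input_mean
        for y_k in z.samples:
            pred = time_update(state, u1, cfg, noise)
            state, _ = measurement_update(pred, y_k, cfg, noise, constrain=False)
            x_ref, P_ref = _plain_ckf_step(x_ref, P_ref, y_k, cfg, noise, u1)
            P_sqrt = state.covariance
            rel = np.linalg.norm(P_sqrt - P_ref) / np.linalg.norm(P_ref)
            assert rel < 1e-9
            assert np.allclose(state.x_hat, x_ref, atol=1e-9)

    def test_measured_variance_never_increases(self, rng, base_params):
        """The update contracts variance along the observed direction."""
        cfg = FilterConfig(measurement="z")
        noise = cfg.noise
        h_vec = np.zeros(12)
        h_vec[1], h_vec[2], h_vec[3] = 1, -1, -1
        state = cfg.initial_state()
        z, _ = simulate(base_params, 1000 / 480, 480.0, seed=22)
        for y_k in z.samples:
            pred = time_update(state, cfg.model.input_mean, cfg, noise)
            var_pred = h_vec @ pred.covariance @ h_vec
            state, _ = measurement_update(pred, y_k, cfg, noise, constrain=False)
            var_post = h_vec @ state.covariance @ h_vec
            assert var_post <= var_pred * (1 + 1e-12)


class TestConstraint:
    @pytest.mark.parametrize(
        "x12,expected", [(-2.0, 0.0), (15.0, 15.0), (150.0, 100.0)]
    )
    def test_interval_projection(self, x12, expected):
        cfg = FilterConfig()
        x = np.r_[np.zeros(11), x12]
        out = apply_constraint(x, cfg)
        assert out[-1] == expected
        assert np.array_equal(out[:11], x[:11])

    def test_gain_estimate_stays_feasible_throughout(self, base_params):
        z, _ = simulate(base_params.with_gains(B=15.0), 1.0, 480.0, seed=3)
        cfg = FilterConfig.for_segment(z, model=base_params)
        trace = run_filter(z, cfg)
        lo, hi = cfg.x12_bounds
        assert np.all(trace.x_hat[:, -1] >= lo)
        assert np.all(trace.x_hat[:, -1] <= hi)


class TestSummarize:
    def _trace(self, i_ba):
        n = len(i_ba)
        return FilterTrace(
            x_hat=np.zeros((n, 12)), i_ba=np.asarray(i_ba, float),
            innovation=np.zeros(n), fs=480.0, config=FilterConfig(),
        )

    def test_constant_trace(self):
        assert summarize_iba(self._trace([3.0] * 100)) == pytest.approx(3.0)

    def test_burn_in_discards_initial_plateau(self):
        trace = self._trace([0.0] * 50 + [10.0] * 50)
        assert summarize_iba(trace) == pytest.approx(10.0)

    def test_linear_ramp_averages_last_half(self):
        trace = self._trace(np.linspace(0, 4, 2000))
        assert summarize_iba(trace) == pytest.approx(3.0, rel=1e-2)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            summarize_iba(self._trace([]))


class TestRecovery:
    def test_constant_gain_recovered_from_noise_free_output(self, base_params):
        """Self-consistency: measurements generated by the filter's own
        discrete model with known constant B are tracked to within 10%."""
        cfg = FilterConfig(measurement="z", r_meas=1e-6)
        B_true = 20.0
        x = np.r_[np.zeros(11), B_true]
        ys = []
        for _ in range(1500):
            x = discrete_dynamics(x, cfg.model.input_mean, cfg)
            ys.append(x[1] - x[2] - x[3])
        from epikf.model import Segment

        seg = Segment(np.array(ys), 480.0, kind="z")
        trace = run_filter(seg, cfg)
        assert trace.i_ba[-1] * cfg.model.A == pytest.approx(B_true, rel=0.10)
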