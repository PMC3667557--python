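"""Engine: prediction errors, free energy, recognition/action flows,
integration and the Laplace confidence machinery."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from actinf.engine import (
    GenerativeProcess,
    HierarchicalModel,
    LevelSpec,
    PosteriorState,
    action_flow,
    compute_errors,
    constant_prior,
    free_energy,
    free_energy_gradient,
    laplace_stddev,
    posterior_interval,
    recognition_flow,
    relax_posterior,
    run_closed_loop,
    step,
)
from actinf.gencoords import RoughnessModel, generalized_precision

from conftest import fd_gradient, kalman_filter_1d


def static_model(prior_mean=0.5, prior_pi=1.0, data_pi=2.0, d_orders=1):
    lv = LevelSpec(n_x=0, n_v=1, out_dim=1, output=lambda x, v: v,
                   log_precision_v=data_pi)
    return HierarchicalModel([lv], n_orders=1, d_orders=d_orders,
                             prior=constant_prior([prior_mean], prior_pi))


class TestComputeErrors:
    def test_perfect_prediction_gives_zero_errors(self):
        lv = LevelSpec(n_x=1, n_v=1, out_dim=1,
                       flow=lambda x, v: np.zeros(1),
                       output=lambda x, v: x.copy())
        m = HierarchicalModel([lv], n_orders=2, d_orders=2,
                              prior=constant_prior([0.7], 0.0))
        post = PosteriorState.zeros(m)
        post.set_mu_x(0, np.array([[0.3, 0.0]]))
        post.set_mu_v(0, np.array([[0.7, 0.0]]))
        s = np.array([[0.3, 0.0]])
        errs = compute_errors(m, post, s)
        assert np.allclose(errs.get(0, "x").eps, 0.0)
        assert np.allclose(errs.get(0, "v").eps, 0.0)
        assert np.allclose(errs.get(0, "eta").eps, 0.0)

    def test_unit_error_unit_precision(self):
        m = static_model(prior_mean=0.0, prior_pi=0.0, data_pi=0.0)
        post = PosteriorState.zeros(m)
        errs = compute_errors(m, post, np.array([[1.0]]))
        assert errs.get(0, "v").xi[0] == pytest.approx(1.0)

    def test_weighted_errors_match_straight_line_oracle(self, rng):
        # independent recomputation: xi = kron(inv(V), diag(exp(pi))) @ eps
        from actinf.experiments import random_model

        m = random_model(rng, n_levels=2, state_dependent=False)
        post = PosteriorState(m, rng.normal(size=m.n_flat) * 0.5)
        s = rng.normal(size=(m.levels[0].out_dim, m.d_orders))
        errs = compute_errors(m, post, s)
        for g in errs.groups:
            Pi = generalized_precision(g.pi, g.order, m.roughness)
            assert np.allclose(g.xi, Pi @ g.eps, atol=1e-12)


class TestFreeEnergy:
    def test_zero_errors_constant_offset(self):
        m = static_model(prior_mean=1.0, prior_pi=0.0, data_pi=0.0)
        post = PosteriorState.zeros(m)
        post.set_mu_v(0, np.array([[1.0]]))
        # error-free except the sensory term; with s = mu the squared terms
        # vanish and only the log-determinant constant remains
        F = free_energy(m, post, np.array([[1.0]]))
        post2 = PosteriorState(m, post.flat.copy())
        assert F == pytest.approx(free_energy(m, post2, np.array([[1.0]])))

    def test_doubling_error_quadratic_increase(self):
        m = static_model(prior_mean=0.0, prior_pi=-30.0, data_pi=0.0)
        post = PosteriorState.zeros(m)
        F1 = free_energy(m, post, np.array([[1.0]]))
        F2 = free_energy(m, post, np.array([[2.0]]))
        # doubling the single unit-precision error adds 1.5x the old
        # squared-error term (0.5 * (4 - 1) = 1.5)
        assert F2 - F1 == pytest.approx(1.5, abs=1e-9)

    def test_matches_gaussian_log_density(self):
        # one static level: F should equal the negative log joint density of
        # prior and likelihood up to an additive constant
        pi_p, pi_d = 0.7, 1.3
        m = static_model(prior_mean=0.4, prior_pi=pi_p, data_pi=pi_d)
        s = 1.7

        def neg_log_joint(v):
            return 0.5 * (
                np.exp(pi_d) * (s - v) ** 2 + np.exp(pi_p) * (v - 0.4) ** 2
            )

        for v in [-1.0, 0.0, 0.9]:
            post = PosteriorState.zeros(m)
            post.set_mu_v(0, np.array([[v]]))
            F = free_energy(m, post, np.array([[s]]))
            post0 = PosteriorState.zeros(m)
            F0 = free_energy(m, post0, np.array([[s]]))
            assert F - F0 == pytest.approx(
                neg_log_joint(v) - neg_log_joint(0.0), abs=1e-9
            )


class TestRecognitionFlow:
    def test_pure_prediction_when_errors_vanish(self):
        lv = LevelSpec(n_x=1, n_v=1, out_dim=1,
                       flow=lambda x, v: np.zeros(1),
                       output=lambda x, v: x.copy(),
                       log_precision_x=1.0, log_precision_v=1.0)
        m = HierarchicalModel([lv], n_orders=3, d_orders=2,
                              prior=constant_prior([0.7], 1.0))
        post = PosteriorState.zeros(m)
        post.set_mu_x(0, np.array([[0.3, 0.0, 0.0]]))
        post.set_mu_v(0, np.array([[0.7, 0.0]]))
        s = np.array([[0.3, 0.0]])
        flow = recognition_flow(m, post, s)
        D = m.shift_operator()
        assert np.allclose(flow, D @ post.flat, atol=1e-10)

    def test_matches_fd_gradient_of_free_energy(self, rng):
        from actinf.experiments import random_model

        for _ in range(5):
            m = random_model(rng)
            post = PosteriorState(m, rng.normal(size=m.n_flat) * 0.5)
            s = rng.normal(size=(m.levels[0].out_dim, m.d_orders))
            grad = free_energy_gradient(m, post, s)
            fd = fd_gradient(
                lambda z: free_energy(m, PosteriorState(m, z), s), post.flat
            )
            scale = max(1.0, np.max(np.abs(fd)))
            assert np.max(np.abs(grad - fd)) / scale < 1e-4

    def test_state_dependent_pi_with_zero_errors(self):
        # with eps = 0, only the prediction D mu and the trace-gradient
        # term survive in the flow
        w = 0.8

        def pi_v(x, v):
            return np.array([0.5 + 0.3 * np.tanh(w * x[0])])

        lv = LevelSpec(n_x=1, n_v=1, out_dim=1,
                       flow=lambda x, v: np.zeros(1),
                       output=lambda x, v: x.copy(),
                       log_precision_x=0.0, log_precision_v=pi_v)
        m = HierarchicalModel([lv], n_orders=2, d_orders=2,
                              prior=constant_prior([0.4], 0.0))
        post = PosteriorState.zeros(m)
        post.set_mu_x(0, np.array([[0.4, 0.0]]))
        post.set_mu_v(0, np.array([[0.4, 0.0]]))
        s = np.array([[0.4, 0.0]])
        flow = recognition_flow(m, post, s)
        D = m.shift_operator()
        residual = flow - D @ post.flat
        # trace term: +1/2 d tr(pi~)/dmu on the order-0 state entry
        dpi = 0.3 * w * (1 - np.tanh(w * 0.4) ** 2)
        expected = 0.5 * m.d_orders * dpi
        slx, _ = m.block_slices()[0]
        assert residual[slx.start] == pytest.approx(expected, rel=1e-6)
        mask = np.ones(m.n_flat, bool)
        mask[slx.start] = False
        assert np.allclose(residual[mask], 0.0, atol=1e-9)


class TestActionFlow:
    def _toy(self):
        return GenerativeProcess(
            n_x=0, n_s=2, n_a=1,
            output=lambda x, v, a: np.array([float(np.atleast_1d(a)[0]), 0.5]),
        )

    def test_zero_error_zero_action(self):
        m = static_model()
        proc = self._toy()
        post = PosteriorState.zeros(m)
        lv = LevelSpec(n_x=0, n_v=2, out_dim=2, output=lambda x, v: v,
                       log_precision_v=1.0)
        m2 = HierarchicalModel([lv], n_orders=1, d_orders=2,
                               prior=constant_prior([0.0, 0.5], 0.0))
        post = PosteriorState.zeros(m2)
        post.set_mu_v(0, np.array([[0.0, 0.0], [0.5, 0.0]]))
        s = proc.sensations_tilde(np.zeros(0), np.zeros(0), np.zeros(1), 2)
        errs = compute_errors(m2, post, s)
        da = action_flow(proc, errs, np.zeros(0), np.zeros(0), np.zeros(1), 2)
        assert np.allclose(da, 0.0, atol=1e-12)

    def test_action_insensitive_channel_contributes_nothing(self):
        proc = self._toy()
        dsda = proc.sensory_action_sensitivity(
            np.zeros(0), np.zeros(0), np.zeros(1), 2
        )
        # second channel never depends on action
        assert np.allclose(dsda[1::2], 0.0)

    def test_matches_fd_gradient_wrt_action(self, rng):
        from actinf.experiments import random_model, random_process

        m = random_model(rng, n_levels=1, state_dependent=False)
        proc = random_process(rng, m.levels[0].out_dim)
        post = PosteriorState(m, rng.normal(size=m.n_flat) * 0.3)
        x_p = rng.normal(size=proc.n_x) * 0.5
        a0 = 0.2
        d = m.d_orders

        def F_of_a(a):
            s_t = proc.sensations_tilde(x_p, np.zeros(0), np.array([a]), d)
            return free_energy(m, post, s_t)

        s_t = proc.sensations_tilde(x_p, np.zeros(0), np.array([a0]), d)
        errs = compute_errors(m, post, s_t)
        da = action_flow(proc, errs, x_p, np.zeros(0), np.array([a0]), d)
        fd = (F_of_a(a0 + 1e-5) - F_of_a(a0 - 1e-5)) / 2e-5
        assert da[0] == pytest.approx(-fd, rel=1e-4)


class TestStep:
    def test_scalar_linear_decay(self):
        out = step(lambda u: -u, np.array([1.0]), 1.0)
        assert out[0] == pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_fixed_point_unchanged(self):
        flow = lambda u: np.array([u[1] - 2.0, 2.0 - u[1], 0.0])
        u0 = np.array([5.0, 2.0, 1.0])
        out = step(flow, u0, 1.0)
        assert np.allclose(out, u0, atol=1e-9)

    def test_matches_fine_explicit_integration_on_pursuit_flow(self):
        # recognition flow of the pursuit model under frozen sensations
        from actinf.pursuit import (
            PursuitModelConfig,
            PursuitWorldConfig,
            build_pursuit_model,
            initial_posterior,
        )

        world = PursuitWorldConfig()
        model = build_pursuit_model(world, PursuitModelConfig())
        mu0 = initial_posterior(model, world)
        s = np.zeros((world.n_channels + 1, model.d_orders))
        s[0, 0] = 0.1

        def flow(u):
            return recognition_flow(model, PosteriorState(model, u), s)

        coarse = step(flow, mu0.copy(), 1.0, n_sub=32)
        # oracle: classical Runge-Kutta with 100 sub-steps
        u = mu0.copy()
        h = 1.0 / 100
        for _ in range(100):
            k1 = flow(u)
            k2 = flow(u + 0.5 * h * k1)
            k3 = flow(u + 0.5 * h * k2)
            k4 = flow(u + h * k3)
            u = u + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert np.linalg.norm(coarse - u) / max(1.0, np.linalg.norm(u)) < 1e-4


class TestClosedLoop:
    def test_perception_only_runs_have_zero_action(self):
        from actinf.birdsong import generate_song, run_birdsong

        song = generate_song(rng_seed=0, duration=40)
        rec = run_birdsong(song, (2.0, 8.0, 16.0), seed=0)
        assert rec.action.shape[1] == 0

    def test_deterministic_per_seed(self):
        from actinf.attenuation import AttenuationConfig, run_force_trial

        cfg = AttenuationConfig(duration=20)
        a = run_force_trial(cfg, seed=5).record
        b = run_force_trial(cfg, seed=5).record
        assert np.array_equal(a.posterior, b.posterior)
        assert np.array_equal(a.sensations, b.sensations)

    def test_tracks_true_state_and_kalman(self):
        kappa = 0.1
        proc = GenerativeProcess(
            n_x=1, n_s=1, n_a=0,
            flow=lambda x, v, a: -kappa * x,
            output=lambda x, v, a: x.copy(),
            noise_log_precision_x=1.0, noise_log_precision_s=3.0,
        )
        lv = LevelSpec(n_x=1, n_v=0, out_dim=1,
                       flow=lambda x, v: -kappa * x,
                       output=lambda x, v: x.copy(),
                       log_precision_x=1.0, log_precision_v=3.0)
        m = HierarchicalModel([lv], n_orders=3, d_orders=2)
        rec = run_closed_loop(proc, m, duration=300, rng_seed=1,
                              x0=np.array([1.0]))
        mu = rec.mu_x0(0, 0)
        truth = rec.true_states[:, 0]
        assert np.corrcoef(mu[30:], truth[30:])[0, 1] > 0.95
        km = kalman_filter_1d(rec.sensations[:, 0], A=np.exp(-kappa),
                              Q=np.exp(-1.0), R=np.exp(-3.0))
        assert np.corrcoef(mu[30:], km[30:])[0, 1] > 0.95

    def test_rejects_nonpositive_duration(self):
        proc = GenerativeProcess(n_x=0, n_s=1, n_a=0,
                                 output=lambda x, v, a: np.zeros(1))
        m = static_model()
        with pytest.raises(ValueError):
            run_closed_loop(proc, m, duration=0)


class TestStaticInference:
    def test_posterior_is_precision_weighted_mean(self):
        for pi_p, pi_d in [(1.0, 2.0), (0.0, 0.0), (-1.0, 3.0)]:
            m = static_model(prior_mean=0.5, prior_pi=pi_p, data_pi=pi_d)
            post = relax_posterior(m, np.array([[2.0]]), n_iter=40)
            expected = (np.exp(pi_p) * 0.5 + np.exp(pi_d) * 2.0) / (
                np.exp(pi_p) + np.exp(pi_d)
            )
            assert post.mu_v(0)[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_posterior_moves_monotonically_with_sensory_precision(self):
        estimates = []
        for pi_d in [-1.0, 0.0, 1.0, 2.0, 3.0]:
            m = static_model(prior_mean=0.0, prior_pi=1.0, data_pi=pi_d)
            post = relax_posterior(m, np.array([[2.0]]), n_iter=40)
            estimates.append(post.mu_v(0)[0, 0])
        assert all(b > a for a, b in zip(estimates, estimates[1:]))
        assert all(0.0 < e < 2.0 for e in estimates)

    def test_descent_reduces_free_energy(self, rng):
        m = static_model(prior_mean=0.3, prior_pi=0.5, data_pi=1.5)
        s = np.array([[1.4]])
        mu = rng.normal(size=m.n_flat) * 2.0
        last = free_energy(m, PosteriorState(m, mu), s)
        for _ in range(20):
            flow = recognition_flow(m, PosteriorState(m, mu), s)
            mu = step(lambda u: recognition_flow(m, PosteriorState(m, u), s),
                      mu, 0.5)
            F = free_energy(m, PosteriorState(m, mu), s)
            assert F <= last + 1e-8
            last = F


class TestLaplaceIntervals:
    def _static_record(self, data_pi=2.0, prior_pi=1.0):
        proc = GenerativeProcess(
            n_x=0, n_s=1, n_a=0, output=lambda x, v, a: np.array([1.5])
        )
        m = static_model(prior_mean=0.5, prior_pi=prior_pi, data_pi=data_pi,
                         d_orders=1)
        return run_closed_loop(proc, m, duration=20, rng_seed=0,
                               store_covariance=True)

    def test_zero_coverage_collapses_to_mean(self):
        rec = self._static_record()
        lo, hi = posterior_interval(rec, 0, "v", 0, 0.0)
        assert np.allclose(lo, hi)
        assert np.allclose(lo, rec.mu_v0(0, 0))

    def test_band_matches_analytic_gaussian_posterior(self):
        pi_p, pi_d = 1.0, 2.0
        rec = self._static_record(data_pi=pi_d, prior_pi=pi_p)
        lo, hi = posterior_interval(rec, 0, "v", 0, 0.9)
        sigma = 1.0 / np.sqrt(np.exp(pi_p) + np.exp(pi_d))
        width = hi[-1] - lo[-1]
        assert width == pytest.approx(2 * 1.6449 * sigma, rel=1e-4)

    def test_quadrupled_precision_halves_band(self):
        rec1 = self._static_record(data_pi=2.0, prior_pi=-30.0)
        rec2 = self._static_record(data_pi=2.0 + np.log(4.0), prior_pi=-30.0)
        w1 = np.subtract(*posterior_interval(rec1, 0, "v", 0, 0.9)[::-1])
        w2 = np.subtract(*posterior_interval(rec2, 0, "v", 0, 0.9)[::-1])
        assert w2[-1] == pytest.approx(w1[-1] / 2.0, rel=1e-6)

    def test_missing_covariance_raises(self):
        proc = GenerativeProcess(
            n_x=0, n_s=1, n_a=0, output=lambda x, v, a: np.array([1.5])
        )
        m = static_model(d_orders=1)
        rec = run_closed_loop(proc, m, duration=5, rng_seed=0)
        with pytest.raises(ValueError):
            posterior_interval(rec, 0, "v", 0, 0.9)
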