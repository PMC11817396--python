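import numpy as np
import pytest
from scipy.linalg import cho_factor, cho_solve

from condyn.diffusion import solve_rank1
from condyn.exceptions import CondynError, InsufficientDataError
from condyn.graph import estimate_adjacency
from condyn.inference import (
    PriorSpec,
    TrainingConfig,
    VariationalPosterior,
    WindowData,
    _loss_and_grad_phi,
    _stack_pairs,
    constraint_prediction,
    constraint_target,
    elbo,
    fit_window,
    infer_dynamics,
    kl_term,
    reconstruction_loss,
    sample_latent,
    split_windows,
)
from condyn.synthetic import BiomarkerSeries


def posterior(nu, psi=None, c=1.0):
    nu = np.asarray(nu, dtype=float)
    psi = np.zeros((nu.size, nu.size)) if psi is None else psi
    return VariationalPosterior(nu, psi, c)


class TestSampling:
    def test_zero_delta_gives_posterior_mode(self):
        q = posterior([0.3, -0.2, 1.0])
        np.testing.assert_allclose(sample_latent(q, np.zeros(3)), np.exp([0.3, -0.2, 1.0]))

    def test_unit_delta_on_first_axis(self):
        q = posterior([0.0, 0.0, 0.0], c=1.0)
        np.testing.assert_allclose(sample_latent(q, np.array([1.0, 0.0, 0.0])),
                                   [np.e, 1.0, 1.0])

    def test_moments_match_parameters(self, rng):
        n = 3
        psi = np.tril(rng.normal(0, 0.3, (n, n)), k=-1)
        q = posterior([0.1, -0.3, 0.2], psi, c=0.5)
        logphi = np.log(sample_latent(q, rng.standard_normal((100_000, n))))
        cov_true = q.covariance()
        se_mean = np.sqrt(np.diag(cov_true) / 1e5)
        assert np.all(np.abs(logphi.mean(0) - q.nu) < 3 * se_mean)
        cov_emp = np.cov(logphi, rowvar=False)
        # moment-based SE for covariance entries, generous fourth-moment bound
        assert np.abs(cov_emp - cov_true).max() < 3 * 3 * cov_true.max() / np.sqrt(1e5)

    def test_nonfinite_delta_rejected(self):
        with pytest.raises(CondynError):
            sample_latent(posterior([0.0, 0.0]), np.array([np.nan, 0.0]))


class TestConstraint:
    def test_target_examples(self):
        assert constraint_target([1.0, 0.0], [0.75, 0.25]) == pytest.approx(0.75)
        x0 = np.array([1.0, 2.0])
        assert constraint_target(x0, x0) == pytest.approx(5.0)
        assert constraint_target([1.0, 0.0], [0.0, 3.0]) == 0.0

    def test_prediction_examples(self):
        assert constraint_prediction([1.0, 1.0], [0.75, 0.25]) == pytest.approx(0.5)
        xt = np.array([1.0, 2.0])
        assert constraint_prediction(xt, xt) == pytest.approx(float(xt @ xt))
        assert constraint_prediction([1.0, 1.0], [1.0, -1.0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(CondynError):
            constraint_target([1.0], [1.0, 2.0])
        with pytest.raises(CondynError):
            constraint_prediction([1.0, 2.0], [1.0])


class TestKL:
    def test_closed_form_examples(self):
        assert kl_term(posterior([0.0, 0.0]), PriorSpec.identity(2)) == pytest.approx(0.0)
        assert kl_term(posterior([1.0, 0.0]), PriorSpec.identity(2)) == pytest.approx(0.5)
        # 0.5*(Tr(S^-1 Psi Psi') + 0 + logdet S - logdet PsiPsi' - N) = 0.5*(1 + 2ln2 - 2)
        assert kl_term(posterior([0.0, 0.0]), PriorSpec(2.0 * np.eye(2))) == pytest.approx(
            0.5 * (1.0 + 2.0 * np.log(2.0) - 2.0)
        )

    def test_nonnegative_for_random_parameters(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 6))
            psi = np.tril(rng.normal(0, 0.5, (n, n)), k=-1)
            q = posterior(rng.normal(0, 1, n), psi, c=float(rng.uniform(0.1, 2.0)))
            B = rng.normal(0, 0.6, (n, n))
            sigma = B @ B.T + 0.5 * np.eye(n)
            assert kl_term(q, PriorSpec(sigma)) >= -1e-12

    def test_matches_monte_carlo(self, rng):
        n = 3
        psi = np.tril(rng.normal(0, 0.3, (n, n)), k=-1)
        q = posterior([0.2, -0.1, 0.4], psi, c=0.4)
        sigma = np.array([[1.0, 0.2, 0.0], [0.2, 1.5, -0.1], [0.0, -0.1, 0.8]])
        prior = PriorSpec(sigma)
        z = q.nu + rng.standard_normal((100_000, n)) @ q.cholesky().T
        cov = q.covariance()

        def logpdf(x, mean, c):
            cf = cho_factor(c, lower=True)
            d = x - mean
            maha = np.einsum("kn,kn->k", d, cho_solve(cf, d.T).T)
            logdet = 2 * np.sum(np.log(np.diag(cf[0])))
            return -0.5 * (maha + logdet + n * np.log(2 * np.pi))

        samples = logpdf(z, q.nu, cov) - logpdf(z, np.zeros(n), sigma)
        mc = samples.mean()
        se = samples.std(ddof=1) / np.sqrt(samples.size)
        assert abs(kl_term(q, prior) - mc) < 3 * se

    def test_non_pd_prior_rejected(self):
        with pytest.raises((CondynError, np.linalg.LinAlgError)):
            kl_term(posterior([0.0, 0.0]), PriorSpec(np.array([[1.0, 2.0], [2.0, 1.0]])))


class TestReconstructionLoss:
    def test_self_consistent_rank1_data_has_zero_loss_for_consensus_latent(self):
        # consensus latent: decay factor 1, and the projection constraint holds exactly
        phi = np.ones(4)
        x0 = np.array([1.0, 0.5, 1.5, 1.0])
        pairs = [(t, solve_rank1(phi, x0, 1.0, t)) for t in (0.3, 0.8)]
        w = WindowData(x0, pairs)
        cfg = TrainingConfig(beta=1.0)
        assert reconstruction_loss(w, [phi], cfg) == pytest.approx(0.0, abs=1e-10)

    def test_constraint_residual_only_for_generating_latent(self):
        phi = np.array([0.7, 1.2, 1.8])
        x0 = np.array([1.0, 0.9, 1.4])
        t = 0.6
        xt = solve_rank1(phi, x0, 1.0, t)
        w = WindowData(x0, [(t, xt)])
        cfg = TrainingConfig(beta=1.0)
        expected_con = (constraint_target(x0, xt) - constraint_prediction(phi, xt)) ** 2
        assert reconstruction_loss(w, [phi], cfg) == pytest.approx(expected_con, rel=1e-10)

    def test_disabling_constraint_leaves_biomarker_error(self, rng):
        phi = rng.lognormal(0, 0.4, 3)
        x0 = rng.uniform(0.5, 1.5, 3)
        xt = rng.uniform(0.5, 1.5, 3)
        w = WindowData(x0, [(0.5, xt)])
        cfg = TrainingConfig(constraint_enabled=False)
        f = solve_rank1(phi, x0, cfg.beta, 0.5)
        assert reconstruction_loss(w, [phi], cfg) == pytest.approx(float(((xt - f) ** 2).sum()))

    def test_hand_computed_two_node_example(self):
        phi = np.array([1.0, 2.0])
        x0 = np.array([1.0, 0.0])
        xt = np.array([0.5, 0.5])
        t = 0.4
        w = WindowData(x0, [(t, xt)])
        cfg = TrainingConfig(beta=1.0)
        f = solve_rank1(phi, x0, 1.0, t)
        expected = float(((xt - f) ** 2).sum()) + (
            constraint_target(x0, xt) - constraint_prediction(phi, xt)
        ) ** 2
        assert reconstruction_loss(w, [phi], cfg) == pytest.approx(expected, rel=1e-12)


class TestGradients:
    def test_analytic_phi_gradient_matches_finite_differences(self, rng):
        M, N = 3, 4
        wins = [WindowData(rng.uniform(0.5, 1.5, N),
                           [(0.4, rng.uniform(0.5, 1.5, N)), (0.9, rng.uniform(0.5, 1.5, N))])]
        X0, XT, TT = _stack_pairs(wins)
        Phi = rng.lognormal(0, 0.3, (M, N))
        _, g, _ = _loss_and_grad_phi(Phi, X0, XT, TT, 1.3, 0.7, 1.0)
        eps = 1e-6
        num = np.zeros_like(Phi)
        for k in range(M):
            for i in range(N):
                for s, mat in ((1, Phi.copy()), (-1, Phi.copy())):
                    mat[k, i] += s * eps
                    val, _, _ = _loss_and_grad_phi(mat, X0, XT, TT, 1.3, 0.7, 1.0,
                                                   want_grad=False)
                    num[k, i] += s * val
        num /= 2 * eps
        assert np.abs(g - num).max() / np.abs(num).max() < 1e-4

    def test_nu_gradient_matches_finite_difference_of_elbo(self, rng):
        """Chain rule through phi = exp(nu + Psi delta), checked on the full objective."""
        N = 3
        win = WindowData(rng.uniform(0.5, 1.5, N), [(0.5, rng.uniform(0.5, 1.5, N))])
        prior = PriorSpec.identity(N)
        cfg = TrainingConfig(beta=1.0)
        delta = rng.standard_normal((6, N))
        psi = np.tril(rng.normal(0, 0.2, (N, N)), k=-1)
        nu = rng.normal(0, 0.3, N)

        def loss_at(nu_vec):
            q = VariationalPosterior(nu_vec, psi.copy(), cfg.diag_const)
            return -elbo(win, q, prior, cfg, delta)

        q = VariationalPosterior(nu.copy(), psi.copy(), cfg.diag_const)
        Phi = sample_latent(q, delta)
        X0, XT, TT = _stack_pairs([win])
        _, g_phi, _ = _loss_and_grad_phi(Phi, X0, XT, TT, cfg.beta, cfg.constraint_weight, 1.0)
        analytic = (Phi * g_phi).sum(0) + nu  # KL gradient is Sigma^-1 nu = nu here
        eps = 1e-6
        for i in range(N):
            e = np.zeros(N)
            e[i] = eps
            num = (loss_at(nu + e) - loss_at(nu - e)) / (2 * eps)
            assert analytic[i] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestFitting:
    def make_rank1_cohort(self, rng, phi_star, n_windows=8, times=(0.3, 0.6, 0.9)):
        wins = []
        for _ in range(n_windows):
            x0 = rng.uniform(0.8, 1.2, phi_star.size)
            wins.append(WindowData(x0, [(t, solve_rank1(phi_star, x0, 1.0, t)) for t in times]))
        return wins

    @pytest.mark.parametrize("seed", range(5))
    def test_parameter_recovery(self, seed):
        rng = np.random.default_rng(seed)
        phi_star = np.array([0.8, 1.4, 0.6, 1.1])
        wins = self.make_rank1_cohort(rng, phi_star)
        cfg = TrainingConfig(epochs=200, samples_per_epoch=64, seed=seed)
        q, trace = fit_window(wins, PriorSpec.identity(4), cfg)
        Phi = sample_latent(q, np.random.default_rng(seed + 100).standard_normal((200, 4)))
        A_hat = estimate_adjacency(Phi)
        A_star = np.outer(phi_star, phi_star) / (phi_star @ phi_star)
        np.fill_diagonal(A_star, 0.0)
        iu = np.triu_indices(4, 1)
        assert np.corrcoef(A_hat[iu], A_star[iu])[0, 1] > 0.9
        assert trace.reconstruction.iloc[-1] < trace.reconstruction.iloc[0]

    def test_loss_decreases_with_and_without_constraint(self, rng):
        phi_star = np.array([1.0, 1.3, 0.7, 1.1])
        wins = self.make_rank1_cohort(rng, phi_star)
        for enabled in (True, False):
            cfg = TrainingConfig(epochs=120, samples_per_epoch=32, seed=3,
                                 constraint_enabled=enabled)
            _, trace = fit_window(wins, PriorSpec.identity(4), cfg)
            assert trace.reconstruction.iloc[-1] < trace.reconstruction.iloc[0]

    def test_zero_epochs_returns_initialization(self, rng):
        wins = self.make_rank1_cohort(rng, np.array([1.0, 1.2, 0.9, 1.1]), n_windows=2)
        cfg = TrainingConfig(epochs=0)
        q, trace = fit_window(wins, PriorSpec.identity(4), cfg)
        X0, XT, _ = _stack_pairs(wins)
        m = np.concatenate([X0, XT]).mean(axis=0)
        np.testing.assert_allclose(np.exp(q.nu), m / np.linalg.norm(m), rtol=1e-12)
        assert np.all(q.psi_offdiag == 0) and len(trace) == 0

    def test_fit_is_deterministic_given_seed(self, rng):
        wins = self.make_rank1_cohort(rng, np.array([1.0, 1.2, 0.9, 1.1]), n_windows=3)
        cfg = TrainingConfig(epochs=30, samples_per_epoch=16, seed=11)
        q1, t1 = fit_window(wins, PriorSpec.identity(4), cfg)
        q2, t2 = fit_window(wins, PriorSpec.identity(4), cfg)
        assert np.array_equal(q1.nu, q2.nu)
        assert np.array_equal(q1.psi_offdiag, q2.psi_offdiag)
        assert t1.equals(t2)


class TestWindows:
    def series(self, times, n=3):
        times = np.asarray(times, dtype=float)
        vals = np.outer(np.arange(1, times.size + 1), np.ones(n))
        return BiomarkerSeries("s", "AD", times, vals)

    def test_even_split_re_zeroes_times(self):
        early, late = split_windows(self.series([0.0, 1.0, 2.0, 3.0]))
        assert [t for t, _ in early.pairs] == [1.0]
        assert [t for t, _ in late.pairs] == [1.0]
        np.testing.assert_allclose(late.x0, 3.0 * np.ones(3))

    def test_odd_count_uses_ceil_rule(self):
        early, late = split_windows(self.series([0.0, 1.0, 2.0, 3.0, 4.0]))
        assert len(early.pairs) == 2 and len(late.pairs) == 1

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError):
            split_windows(self.series([0.0, 1.0, 2.0]))


class TestInferDynamics:
    def cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        phi_star = np.array([0.9, 1.3, 0.7, 1.1])
        out = []
        for s in range(6):
            x0 = rng.uniform(0.8, 1.2, 4)
            times = np.array([0.0, 0.3, 0.6, 0.9])
            vals = [x0] + [solve_rank1(phi_star, x0, 1.0, t) for t in times[1:]]
            out.append(BiomarkerSeries(f"s{s}", "AD", times, np.array(vals)))
        return out

    def test_deterministic_and_structured_output(self):
        cohort = self.cohort()
        cfg = TrainingConfig(epochs=25, samples_per_epoch=16, seed=5)
        fits1 = infer_dynamics(cohort, None, cfg)
        fits2 = infer_dynamics(cohort, None, cfg)
        assert len(fits1) == 2
        for f1, f2 in zip(fits1, fits2):
            assert np.array_equal(f1.adjacency, f2.adjacency)
            np.testing.assert_allclose(f1.laplacian.sum(axis=1), 0.0, atol=1e-9)

    def test_empty_cohort_rejected(self):
        with pytest.raises(CondynError):
            infer_dynamics([], None, TrainingConfig())
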