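import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import norm

import seqthresh as st
from seqthresh.intervals import ExpandedData, IntervalGrid, expand_survival
from seqthresh.samplers import (LassoState, SamplerConfig, fit, sample_beta,
                                sample_gamma, sample_liabilities,
                                sample_snp_effects)


def truncated_normal_mean(eta, gamma, y):
    """Closed-form mean of N(eta,1) truncated at gamma (lower for y=1)."""
    a = gamma - eta
    if y == 1:
        return eta + norm.pdf(a) / norm.sf(a)
    return eta - norm.pdf(a) / norm.cdf(a)


def single_interval_expanded(y):
    y = np.asarray(y, dtype=int)
    return ExpandedData(np.arange(len(y)), np.ones(len(y), dtype=int), y)


class TestLiabilities:
    def test_truncation_respected(self, rng):
        exp = single_interval_expanded(np.zeros(500))
        u = sample_liabilities(exp, np.array([0.0]), np.zeros(500), rng)
        assert (u < 0).all()
        exp1 = single_interval_expanded(np.ones(500))
        u1 = sample_liabilities(exp1, np.array([0.0]), np.zeros(500), rng)
        assert (u1 >= 0).all()

    def test_far_tail_is_finite(self, rng):
        exp = single_interval_expanded(np.ones(100))
        u = sample_liabilities(exp, np.array([10.0]), np.zeros(100), rng)
        assert np.isfinite(u).all()
        assert (u >= 10.0).all()

    @pytest.mark.parametrize("gamma,eta,y", [
        (0.0, 0.0, 1), (0.0, 0.0, 0), (1.5, -0.5, 1), (-2.0, 1.0, 0),
        (10.0, 0.0, 1),
    ])
    def test_matches_closed_form_mean(self, gamma, eta, y, rng):
        n = 20000
        exp = single_interval_expanded(np.full(n, y))
        u = sample_liabilities(exp, np.array([gamma]), np.full(n, eta), rng)
        se = u.std(ddof=1) / np.sqrt(n)
        assert abs(u.mean() - truncated_normal_mean(eta, gamma, y)) < 3 * se


class TestGamma:
    def test_centred_latents_give_centred_cutoff(self, rng):
        n = 200
        latents = np.linspace(-1, 1, n)   # mean 0
        k_rec = np.ones(n, dtype=int)
        draws = np.array([
            sample_gamma(latents, k_rec, np.zeros(n), np.zeros(1), rng)[0]
            for _ in range(2000)])
        assert abs(draws.mean()) < 4 * draws.std() / np.sqrt(len(draws))
        assert draws.std() == pytest.approx(np.sqrt(1 / (n + 0.01)), rel=0.1)

    def test_single_record_scale_one(self, rng):
        draws = np.array([
            sample_gamma(np.array([0.7]), np.array([1]), np.array([0.0]),
                         np.zeros(1), rng, prior_var=np.inf)[0]
            for _ in range(4000)])
        assert draws.std() == pytest.approx(1.0, rel=0.05)

    def test_empty_interval_unchanged_with_warning(self, rng, caplog):
        gamma = np.array([0.5, -1.2])
        with caplog.at_level("WARNING"):
            out = sample_gamma(np.array([0.1]), np.array([1]),
                               np.array([0.0]), gamma, rng)
        assert out[1] == -1.2
        assert "no records" in caplog.text


class TestBeta:
    def test_vague_prior_matches_ols(self, rng):
        x = rng.standard_normal(300)
        latents = 2.0 * x + rng.standard_normal(300)
        X = x[:, None]
        draws = np.array([sample_beta(latents, X, 1e8, rng)[0]
                          for _ in range(1500)])
        ols = float(x @ latents / (x @ x))
        assert draws.mean() == pytest.approx(ols, abs=0.02)

    def test_tight_prior_dominates(self, rng):
        x = rng.standard_normal(100)
        latents = 2.0 * x
        draws = np.array([sample_beta(latents, x[:, None], 1e-6, rng)[0]
                          for _ in range(500)])
        assert abs(draws.mean()) < 0.01

    def test_orthonormal_design_diagonal_covariance(self, rng):
        q, n = 3, 60
        A = rng.standard_normal((n, q))
        Q, _ = np.linalg.qr(A)
        latents = rng.standard_normal(n)
        draws = np.array([sample_beta(latents, Q, 4.0, rng)
                          for _ in range(6000)])
        cov = np.cov(draws.T)
        expected_var = 1.0 / (1.0 + 1.0 / 4.0)
        assert np.allclose(np.diag(cov), expected_var, rtol=0.15)
        off = cov[~np.eye(q, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_collinear_columns_error(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, x])
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_like_check(X)


def fit_like_check(X):
    from seqthresh.samplers import _check_covariate_rank
    _check_covariate_rank(X, ["a", "b"])


class TestSnpEffects:
    def test_tiny_tau_shrinks_to_zero(self, rng):
        W = rng.standard_normal((50, 4))
        latents = rng.standard_normal(50) + W @ np.array([1.0, -1, 2, 0.5])
        state = LassoState(lambda2=1.0, tau2=np.full(4, 1e-10))
        eff, _ = sample_snp_effects(latents, W, state, rng,
                                    update_lambda=False)
        assert np.abs(eff).max() < 0.01

    def test_zero_variance_marker_fixed_at_zero(self, rng):
        W = np.column_stack([np.zeros(30), rng.standard_normal(30)])
        state = LassoState(lambda2=1.0, tau2=np.ones(2))
        eff, _ = sample_snp_effects(rng.standard_normal(30), W, state, rng,
                                    effects=np.array([5.0, 0.0]))
        assert eff[0] == 0.0

    def test_lambda_conditional_shape_rate_replay(self):
        """The lambda2 draw must come from Gamma(P+a, b + sum(tau2)/2)."""
        rng = np.random.default_rng(77)
        W = np.random.default_rng(1).standard_normal((6, 2))
        latents = np.random.default_rng(2).standard_normal(6)
        state = LassoState(lambda2=2.0, tau2=np.array([0.5, 1.5]))
        a0, b0 = 0.3, 0.7
        eff, new = sample_snp_effects(latents, W, state, rng,
                                      lasso_shape=a0, lasso_rate=b0)
        # replay the generator stream with the same seed
        rng2 = np.random.default_rng(77)
        rng2.standard_normal(2)                       # effect draws
        mu = np.clip(np.sqrt(state.lambda2 / np.maximum(eff ** 2, 1e-20)),
                     1e-10, 1e8)
        inv_tau2 = rng2.wald(mu, state.lambda2)
        np.testing.assert_allclose(new.tau2,
                                   1.0 / np.maximum(inv_tau2, 1e-12))
        expected = rng2.gamma(2 + a0, 1.0 / (b0 + new.tau2.sum() / 2.0))
        assert new.lambda2 == pytest.approx(expected)

    def test_gibbs_matches_grid_posterior_1snp(self, rng):
        """3-record, 1-SNP marginal vs 2-D numerical integration over
        (effect, tau2) with lambda2 held fixed."""
        u = np.array([0.5, -0.2, 1.0])
        w = np.array([[1.0], [0.0], [-1.0]])
        lam2 = 2.0
        state = LassoState(lambda2=lam2, tau2=np.array([1.0]))
        eff = np.zeros(1)
        draws = []
        for it in range(15000):
            eff, state = sample_snp_effects(u, w, state, rng, effects=eff,
                                            update_lambda=False)
            if it >= 1000:
                draws.append(eff[0])
        draws = np.asarray(draws)
        a_grid = np.linspace(-3, 3, 801)
        t_grid = np.exp(np.linspace(np.log(1e-5), np.log(50), 800))
        A, T = np.meshgrid(a_grid, t_grid, indexing="ij")
        ss = ((u[:, None, None] - w[:, 0][:, None, None] * A[None]) ** 2).sum(0)
        logp = -0.5 * ss - 0.5 * np.log(T) - A ** 2 / (2 * T) - lam2 * T / 2
        wts = np.exp(logp - logp.max())
        marg = np.trapezoid(wts, t_grid, axis=1)
        marg /= np.trapezoid(marg, a_grid)
        m = np.trapezoid(marg * a_grid, a_grid)
        sd = np.sqrt(np.trapezoid(marg * (a_grid - m) ** 2, a_grid))
        mc_se = draws.std() / np.sqrt(len(draws) / 10)   # autocorr slack
        assert draws.mean() == pytest.approx(m, abs=max(4 * mc_se, 0.02))
        assert draws.std() == pytest.approx(sd, rel=0.1)


class TestFit:
    def _sim(self, **kw):
        base = dict(n_patients=200, n_snps=20, n_intervals=3, snp_h2=0.1,
                    n_causal=5, event_fraction=0.4, ld_rho=0.0, seed=8)
        base.update(kw)
        spec = st.SimSpec(**base)
        cohort, truth = st.simulate_cohort(spec)
        return cohort, st.default_grid(spec), truth

    def test_posterior_matches_probit_quadrature(self, cohort_factory, rng):
        """Full probit Gibbs vs 2-D quadrature over (cutoff, coefficient)."""
        n = 25
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 - ndtr(0.3 - 0.8 * x)).astype(int)
        cohort = cohort_factory(np.where(y == 1, 5.0, 10.0), y,
                                covariates=x[:, None])
        grid = IntervalGrid(np.array([0.0, 10.0, np.inf]))
        vb = vg = 4.0
        cfg = SamplerConfig(n_iter=20000, n_burnin=2000, thin=2, seed=3,
                            beta_prior_var=vb, gamma_prior_var=vg)
        res = fit(cohort, grid, "cpp", cfg)
        gs = np.linspace(-4, 4, 301)
        bs = np.linspace(-4, 4, 301)
        G, B = np.meshgrid(gs, bs, indexing="ij")
        logp = -G ** 2 / (2 * vg) - B ** 2 / (2 * vb)
        for i in range(n):
            s = ndtr(G - x[i] * B)
            logp += np.log(np.where(y[i] == 1, 1 - s, s) + 1e-300)
        w = np.exp(logp - logp.max())
        w /= w.sum()
        assert res.gamma_mean[0] == pytest.approx((w * G).sum(), abs=0.06)
        assert res.beta_mean[0] == pytest.approx((w * B).sum(), abs=0.08)

    def test_covariate_recovery(self):
        spec = st.SimSpec(n_patients=500, n_snps=2, n_intervals=4,
                          snp_h2=0.0, n_causal=0,
                          cpp_effects=(1.0, 0, 0, 0, 0, 0),
                          event_fraction=0.4, ld_rho=0.0, seed=21)
        cohort, truth = st.simulate_cohort(spec)
        cfg = SamplerConfig(n_iter=800, n_burnin=300, thin=2, seed=4)
        res = fit(cohort, st.default_grid(spec), "cpp", cfg)
        assert abs(res.beta_mean[0] - 1.0) <= 0.25

    def test_lasso_shrinks_relative_to_flat_prior(self):
        cohort, grid, _ = self._sim(n_patients=80, n_snps=10, snp_h2=0.0,
                                    n_causal=0)
        cfg = SamplerConfig(n_iter=600, n_burnin=200, thin=2, seed=5)
        lasso = fit(cohort, grid, "snp", cfg)
        flat = cohort_with_snps_as_covariates(cohort)
        flat_fit = fit(flat, grid, "cpp", cfg)
        assert (np.abs(lasso.snp_effect_mean).mean()
                < np.abs(flat_fit.beta_mean).mean())

    def test_deterministic_under_seed(self):
        cohort, grid, _ = self._sim()
        cfg = SamplerConfig(n_iter=120, n_burnin=40, thin=2, seed=9)
        r1 = fit(cohort, grid, "cpp_snp", cfg)
        r2 = fit(cohort, grid, "cpp_snp", cfg)
        np.testing.assert_array_equal(r1.gamma_mean, r2.gamma_mean)
        np.testing.assert_array_equal(r1.beta_mean, r2.beta_mean)
        np.testing.assert_array_equal(r1.snp_effect_mean, r2.snp_effect_mean)
        assert r1.lambda_mean == r2.lambda_mean

    def test_residual_variance_fixed(self):
        cohort, grid, _ = self._sim()
        cfg = SamplerConfig(n_iter=60, n_burnin=20, thin=2, seed=1)
        res = fit(cohort, grid, "cpp", cfg)
        assert res.sigma2_e == 1.0
        with pytest.raises(ValueError):
            st.FitResult(model="cpp", gamma_mean=np.zeros(1),
                         beta_mean=np.zeros(1),
                         snp_effect_mean=np.zeros(0), lambda_mean=None,
                         sigma2_e=0.9, n_iter=1, n_burnin=0, thin=1, seed=0)

    def test_linear_predictor_decomposes_additively(self):
        cohort, grid, _ = self._sim()
        cfg = SamplerConfig(n_iter=120, n_burnin=40, thin=2, seed=2)
        res = fit(cohort, grid, "cpp_snp", cfg)
        joint = res.predict(covariates=cohort.covariates,
                            genotypes=cohort.genotypes)
        cov_part = cohort.covariates @ res.beta_mean
        snp_part = (cohort.genotypes - res.snp_center) @ res.snp_effect_mean
        np.testing.assert_allclose(joint, cov_part + snp_part, rtol=0, atol=0)

    def test_missing_genotypes_rejected(self):
        cohort, grid, _ = self._sim()
        cohort.genotypes[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            fit(cohort, grid, "snp",
                SamplerConfig(n_iter=10, n_burnin=1, thin=1))

    def test_fitresult_json_roundtrip(self, tmp_path):
        cohort, grid, _ = self._sim()
        cfg = SamplerConfig(n_iter=60, n_burnin=20, thin=2, seed=3)
        res = fit(cohort, grid, "cpp_snp", cfg)
        path = tmp_path / "fit.json"
        res.to_json(path)
        back = st.FitResult.from_json(path)
        np.testing.assert_allclose(back.snp_effect_mean, res.snp_effect_mean)
        np.testing.assert_allclose(back.boundaries[:-1], res.boundaries[:-1])
        assert np.isinf(back.boundaries[-1])


def cohort_with_snps_as_covariates(cohort):
    from seqthresh.io import Cohort
    g = cohort.genotypes - cohort.genotypes.mean(axis=0)
    return Cohort(patient_ids=cohort.patient_ids,
                  genotypes=np.zeros((cohort.n, 0)), snp_ids=[],
                  snp_chroms=np.array([], dtype=str),
                  covariates=g, covariate_names=list(cohort.snp_ids),
                  time=cohort.time, event=cohort.event)


class TestGewekeJointDistribution:
    """Prior-predictive/successive-conditional agreement of the full kernel.

    Drawing parameters from the prior and data from the model, then
    alternating one Gibbs scan with data regeneration, must leave the
    parameter marginals at their prior values (N=30, P=5, K=2 instance).
    The grid carries one extra open-ended interval in which every survivor
    is censored, so that all K modelled interval trials are fully observed
    and the generator's observation model matches the kernel's
    drop-partial-interval censoring convention exactly.
    """

    N, P, K = 30, 5, 2
    VB = VG = 0.5
    AL, BL = 3.0, 3.0          # Gamma prior on lambda2 (mean 1)
    M = 6000

    def _design(self):
        r = np.random.default_rng(1000)
        x = (r.random(self.N) < 0.5).astype(float)
        x -= x.mean()
        W = r.integers(0, 3, size=(self.N, self.P)).astype(float)
        W -= W.mean(axis=0)
        return x[:, None], W

    def _draw_prior(self, r):
        # gamma has K modelled cutoffs + 1 inert one for the dump interval
        gamma = r.normal(0, np.sqrt(self.VG), self.K + 1)
        beta = r.normal(0, np.sqrt(self.VB), 1)
        lam2 = r.gamma(self.AL, 1 / self.BL)
        tau2 = r.exponential(2.0 / lam2, self.P)
        eff = r.normal(0, np.sqrt(tau2))
        return gamma, beta, eff, LassoState(lam2, np.maximum(tau2, 1e-12))

    def _draw_data(self, X, W, gamma, beta, eff, r):
        eta = (X @ beta + W @ eff)
        # survivors of all K trials are censored inside the dump interval,
        # having fully survived intervals 1..K
        time = np.full(self.N, self.K + 0.25)
        event = np.zeros(self.N, dtype=int)
        alive = np.ones(self.N, dtype=bool)
        for k in range(1, self.K + 1):
            p_ev = 1 - ndtr(gamma[k - 1] - eta)
            ev = alive & (r.random(self.N) < p_ev)
            time[ev] = k - 0.5
            event[ev] = 1
            alive &= ~ev
        return time, event

    def test_kernel_preserves_prior_marginals(self, caplog):
        import logging
        caplog.set_level(logging.ERROR, logger="seqthresh.samplers")
        X, W = self._design()
        grid = IntervalGrid(np.concatenate(
            (np.arange(self.K + 1, dtype=float), [np.inf])))
        r = np.random.default_rng(2024)
        # marginal-conditional: independent prior draws
        prior_stats = []
        for _ in range(self.M):
            gamma, beta, eff, state = self._draw_prior(r)
            prior_stats.append([gamma[0], beta[0], state.lambda2,
                                np.sum(eff ** 2)])
        prior_stats = np.array(prior_stats)
        # successive-conditional: regenerate data, one Gibbs scan
        gamma, beta, eff, state = self._draw_prior(r)
        succ = []
        for _ in range(self.M):
            time, event = self._draw_data(X, W, gamma, beta, eff, r)
            exp = expand_survival(time, event, grid)
            pat = exp.record_patient
            eta_pat = X @ beta + W @ eff
            u = sample_liabilities(exp, gamma, eta_pat, r)
            eta_rec = eta_pat[pat]
            z = u - gamma[exp.record_interval - 1]
            gamma = sample_gamma(u, exp.record_interval, eta_rec, gamma, r,
                                 prior_var=self.VG)
            # the dump interval never has records: redraw its cutoff from
            # the prior so its marginal stays correct
            gamma[self.K] = r.normal(0, np.sqrt(self.VG))
            u = z + gamma[exp.record_interval - 1]
            g_rec = (W @ eff)[pat]
            beta = sample_beta(u, X[pat], self.VB, r, offset=g_rec)
            xb_rec = (X @ beta)[pat]
            eff, state = sample_snp_effects(
                u, W[pat], state, r, offset=xb_rec, effects=eff,
                lasso_shape=self.AL, lasso_rate=self.BL)
            succ.append([gamma[0], beta[0], state.lambda2,
                         np.sum(eff ** 2)])
        succ = np.array(succ)
        for j, name in enumerate(["gamma1", "beta", "lambda2", "sum_eff2"]):
            se_p = prior_stats[:, j].std(ddof=1) / np.sqrt(self.M)
            se_s = _batch_se(succ[:, j])
            tol = 5 * np.hypot(se_p, se_s)
            diff = abs(prior_stats[:, j].mean() - succ[:, j].mean())
            assert diff < tol, f"{name}: diff {diff:.4f} > tol {tol:.4f}"


def _batch_se(x, n_batches=40):
    b = len(x) // n_batches
    means = x[:b * n_batches].reshape(n_batches, b).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)
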