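"""Gibbs sampler for the multivariate mixed model: conditionals vs dense
Gaussian oracles, closed-form limits, HPD/significance/ESS machinery, and a
joint-correctness (forward vs successive-conditional) check."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import invwishart

from siblock import (
    GibbsConfig,
    MLMEPriors,
    MultivariateMixedLM,
    effective_sample_size,
    flag_significance,
    hpd_interval,
)
from siblock.mlme import MLMEError


def _tiny_model(seed=0, n_clusters=3, sibs=2, p=2, n_cov=1):
    rng = np.random.default_rng(seed)
    N = n_clusters * sibs
    groups = np.repeat(np.arange(n_clusters), sibs)
    T = np.tile([1.0] + [0.0] * (sibs - 1), n_clusters)
    X = rng.normal(size=(N, n_cov)) if n_cov else None
    Y = rng.normal(size=(N, p))
    return MultivariateMixedLM(Y, T, X, groups), rng


class TestHPD:
    def test_identical_draws_zero_width(self):
        lo, hi = hpd_interval(np.full(25, 3.14), 0.95)
        assert (lo, hi) == (3.14, 3.14)

    def test_uniform_grid_lowest_start_tie_break(self):
        lo, hi = hpd_interval(np.arange(1, 101, dtype=float), 0.95)
        assert (lo, hi) == (1.0, 95.0)

    def test_standard_normal_quantiles(self):
        draws = np.random.default_rng(42).standard_normal(100_000)
        lo, hi = hpd_interval(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_never_wider_than_equal_tailed(self):
        rng = np.random.default_rng(7)
        for draws in (
            rng.standard_normal(5000),
            rng.gamma(2.0, size=5000),  # skewed: HPD strictly shorter
            rng.uniform(size=5000),
        ):
            lo, hi = hpd_interval(draws, 0.95)
            eq_lo, eq_hi = np.quantile(draws, [0.025, 0.975])
            assert (hi - lo) <= (eq_hi - eq_lo) + 1e-12

    def test_too_few_draws(self):
        with pytest.raises(MLMEError):
            hpd_interval(np.arange(10.0), 0.95)

    def test_matches_arviz_hdi(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(8)
        for draws in (rng.standard_normal(5000), rng.gamma(3.0, size=5000)):
            lo, hi = hpd_interval(draws, 0.95)
            ref_lo, ref_hi = np.asarray(arviz.hdi(draws, hdi_prob=0.95))
            assert lo == pytest.approx(ref_lo, abs=0.02)
            assert hi == pytest.approx(ref_hi, abs=0.02)


class TestSignificanceRule:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (0.61, 1.97, True),  # entirely positive
            (-0.59, 2.15, False),  # straddles zero
            (-0.24, -0.04, True),  # entirely negative
            (0.0, 1.0, False),  # zero on the boundary is not excluded
        ],
    )
    def test_hpd_excludes_zero(self, lo, hi, expected):
        assert bool(flag_significance(lo, hi)) is expected


class TestESS:
    def test_iid_chain_near_n(self):
        n = 20_000
        x = np.random.default_rng(3).standard_normal(n)
        assert effective_sample_size(x) == pytest.approx(n, rel=0.15)

    def test_ar1_matches_closed_form(self):
        n, rho = 40_000, 0.9
        rng = np.random.default_rng(4)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.25)

    def test_constant_chain_flagged(self):
        assert np.isnan(effective_sample_size(np.ones(100)))


class TestCoefficientConditional:
    def test_moments_match_dense_gaussian_oracle(self):
        # independent route: stack vec(Y) = (I_p x Z) vec(B) + noise and
        # condition the joint Gaussian densely
        model, rng = _tiny_model(seed=5, n_clusters=3, sibs=2, p=2, n_cov=1)
        N, p, q = model.n_obs, model.n_outcomes, model.n_coef
        A = np.random.default_rng(8).normal(size=(p, p))
        sigma_e = A @ A.T + 0.5 * np.eye(p)
        v0 = 2.0
        b_exp = np.zeros((N, p))
        mean, prec = model.coef_conditional(b_exp, np.linalg.inv(sigma_e), v0)
        big_design = np.kron(np.eye(p), model.design)
        W = np.kron(np.linalg.inv(sigma_e), np.eye(N))
        P_oracle = big_design.T @ W @ big_design + np.eye(q * p) / v0
        mean_oracle = np.linalg.solve(
            P_oracle, big_design.T @ W @ model.endog.reshape(-1, order="F")
        )
        np.testing.assert_allclose(mean.reshape(-1, order="F"), mean_oracle, atol=1e-8)
        np.testing.assert_allclose(np.linalg.inv(prec), np.linalg.inv(P_oracle), atol=1e-8)

    def test_flat_prior_identity_covariance_gives_ols(self):
        model, _ = _tiny_model(seed=6, n_clusters=5, sibs=2, p=2, n_cov=2)
        mean, _ = model.coef_conditional(
            np.zeros((model.n_obs, model.n_outcomes)), np.eye(2), 1e12
        )
        ols = np.linalg.lstsq(model.design, model.endog, rcond=None)[0]
        np.testing.assert_allclose(mean, ols, atol=1e-6)

    def test_dogmatic_prior_collapses_draw_to_zero(self):
        model, rng = _tiny_model(seed=7)
        draw = model._update_coefficients(
            np.zeros((model.n_obs, model.n_outcomes)), np.eye(2), 1e-12, rng
        )
        assert np.abs(draw).max() < 1e-4


class TestRandomEffectConditional:
    @staticmethod
    def _hand_matrices():
        sigma_b = np.array([[1.0, 0.3], [0.3, 0.5]])
        sigma_e = np.array([[0.8, -0.2], [-0.2, 1.1]])
        return sigma_b, sigma_e

    def test_moments_match_joint_gaussian_conditioning(self):
        # oracle: condition (b_j, residuals) jointly, Cov built from first
        # principles: resid_i = b_j + eps_i
        model, _ = _tiny_model(seed=9, n_clusters=2, sibs=3, p=2, n_cov=0)
        sigma_b, sigma_e = self._hand_matrices()
        fitted = np.zeros_like(model.endog)
        means, covs = model.ranef_conditional(fitted, sigma_b, sigma_e)
        n, p = 3, 2
        cov_br = np.tile(sigma_b, (1, n))  # Cov(b, resid stack)
        cov_rr = np.kron(np.ones((n, n)), sigma_b) + np.kron(np.eye(n), sigma_e)
        for j in range(2):
            r = model.endog[model.group_codes == j].reshape(-1)
            gain = cov_br @ np.linalg.inv(cov_rr)
            np.testing.assert_allclose(means[j], gain @ r, atol=1e-10)
            np.testing.assert_allclose(
                covs[j], sigma_b - gain @ cov_br.T, atol=1e-10
            )

    def test_draws_match_conditional_moments(self):
        model, _ = _tiny_model(seed=10, n_clusters=2, sibs=2, p=2, n_cov=0)
        sigma_b, sigma_e = self._hand_matrices()
        fitted = np.zeros_like(model.endog)
        means, covs = model.ranef_conditional(fitted, sigma_b, sigma_e)
        rng = np.random.default_rng(11)
        draws = np.array(
            [
                model._update_random_effects(
                    fitted, np.linalg.inv(sigma_b), np.linalg.inv(sigma_e), rng
                )
                for _ in range(20_000)
            ]
        )
        mc_se = np.sqrt(np.array([np.diag(c) for c in covs]) / draws.shape[0])
        np.testing.assert_array_less(np.abs(draws.mean(axis=0) - means), 4 * mc_se)
        emp_cov = np.cov(draws[:, 0, :].T)
        np.testing.assert_allclose(emp_cov, covs[0], atol=0.05)

    def test_tiny_sigma_b_pins_intercepts_to_zero(self):
        model, rng = _tiny_model(seed=12)
        b = model._update_random_effects(
            np.zeros_like(model.endog),
            np.linalg.inv(1e-12 * np.eye(2)),
            np.eye(2),
            rng,
        )
        assert np.abs(b).max() < 1e-4

    def test_data_dominant_limit_gives_cluster_mean_residual(self):
        model, _ = _tiny_model(seed=13, n_clusters=2, sibs=4, p=2, n_cov=0)
        sigma_e = 1e-8 * np.eye(2)
        means, _ = model.ranef_conditional(
            np.zeros_like(model.endog), np.eye(2), sigma_e
        )
        for j in range(2):
            cluster_mean = model.endog[model.group_codes == j].mean(axis=0)
            np.testing.assert_allclose(means[j], cluster_mean, atol=1e-6)


class TestCovarianceUpdates:
    def test_posterior_mean_consistent_at_large_j(self):
        p, J = 2, 5000
        truth = np.array([[1.5, 0.6], [0.6, 1.0]])
        rng = np.random.default_rng(14)
        b = rng.multivariate_normal(np.zeros(p), truth, size=J)
        scale = np.eye(p) + b.T @ b
        draws = invwishart.rvs(df=p + 2 + J, scale=scale, size=200, random_state=rng)
        np.testing.assert_allclose(draws.mean(axis=0), truth, rtol=0.05)

    def test_prior_draw_deterministic_under_seed(self):
        d1 = MultivariateMixedLM._draw_inverse_wishart(
            10, np.eye(10), np.random.default_rng(15), "prior"
        )
        d2 = MultivariateMixedLM._draw_inverse_wishart(
            10, np.eye(10), np.random.default_rng(15), "prior"
        )
        np.testing.assert_array_equal(d1, d2)
        assert np.linalg.eigvalsh(d1).min() > 0


class TestFit:
    def test_flat_prior_fixed_effects_recover_ols(self):
        # no random effects, known residual covariance: the beta posterior
        # is exact and iid, so its mean must sit on per-outcome OLS
        rng = np.random.default_rng(16)
        N, p = 40, 2
        T = rng.integers(0, 2, N).astype(float)
        Y = np.column_stack([1.0 + 0.8 * T, -0.5 * T]) + rng.normal(0, 1.0, (N, p))
        model = MultivariateMixedLM(Y, T, None, groups=np.arange(N) % 5)
        res = model.fit(
            priors=MLMEPriors(beta_prior_variance=1e9, iw_df=p),
            config=GibbsConfig(n_iter=3000, burn_in=500, seed=17),
            random_effects=False,
            fix_sigma_e=np.eye(p),
        )
        ols = np.linalg.lstsq(model.design, Y, rcond=None)[0]
        n_draws = res.chains["beta"].shape[0]
        sd = res.chains["beta"].std(axis=0, ddof=1)
        np.testing.assert_array_less(
            np.abs(res.posterior_mean.to_numpy() - ols), 4 * sd / np.sqrt(n_draws) + 1e-9
        )

    def test_ridge_form_conjugate_posterior_single_outcome(self):
        # informative prior: mean must match (X'X/s2 + I/v0)^-1 X'y / s2
        rng = np.random.default_rng(18)
        N, v0, s2 = 30, 0.5, 2.0
        T = rng.integers(0, 2, N).astype(float)
        y = (0.3 + 1.2 * T + rng.normal(0, np.sqrt(s2), N))[:, None]
        model = MultivariateMixedLM(y, T, None, groups=np.arange(N) % 3)
        res = model.fit(
            priors=MLMEPriors(beta_prior_variance=v0, iw_df=1),
            config=GibbsConfig(n_iter=4000, burn_in=500, seed=19),
            random_effects=False,
            fix_sigma_e=np.array([[s2]]),
        )
        Z = model.design
        ridge = np.linalg.solve(Z.T @ Z / s2 + np.eye(2) / v0, Z.T @ y / s2)
        n_draws = res.chains["beta"].shape[0]
        sd = res.chains["beta"].std(axis=0, ddof=1)
        np.testing.assert_array_less(
            np.abs(res.posterior_mean.to_numpy() - ridge), 3 * sd / np.sqrt(n_draws)
        )

    def test_null_truth_posterior_centred_at_zero(self):
        # bias of the exposure posterior mean across replicates under a
        # zero-effect truth stays within Monte-Carlo error
        from siblock import CohortSpec, generate_cohort, generate_outcomes

        n_out = 10
        means = []
        for rep in range(6):
            spec = CohortSpec(
                n_mothers=80, seed=100 + rep, beta1_true=np.zeros(n_out)
            )
            sheet, params = generate_cohort(spec)
            Y = generate_outcomes(sheet, params, seed=200 + rep)
            model = MultivariateMixedLM.from_dataframes(Y, sheet)
            res = model.fit(config=GibbsConfig(n_iter=1200, burn_in=400, seed=rep))
            means.append(res.posterior_mean.loc["exposure"].to_numpy())
        means = np.array(means)
        se = means.std(axis=0, ddof=1) / np.sqrt(len(means))
        assert (np.abs(means.mean(axis=0)) < 3 * se + 0.05).all()

    def test_within_cluster_permutation_leaves_conditionals_unchanged(self):
        rng = np.random.default_rng(20)
        N, p = 12, 2
        groups = np.repeat(np.arange(6), 2)
        T = np.tile([1.0, 0.0], 6)
        Y = rng.normal(size=(N, p))
        m1 = MultivariateMixedLM(Y, T, None, groups)
        # swap the two children of every cluster
        perm = np.arange(N).reshape(6, 2)[:, ::-1].reshape(-1)
        m2 = MultivariateMixedLM(Y[perm], T[perm], None, groups[perm])
        se_inv = np.linalg.inv(np.array([[1.0, 0.2], [0.2, 0.7]]))
        mean1, prec1 = m1.coef_conditional(np.zeros((N, p)), se_inv, 10.0)
        mean2, prec2 = m2.coef_conditional(np.zeros((N, p)), se_inv, 10.0)
        np.testing.assert_allclose(mean1, mean2, atol=1e-10)
        np.testing.assert_allclose(prec1, prec2, atol=1e-10)
        r1, _ = m1.ranef_conditional(np.zeros((N, p)), np.eye(p), np.eye(p))
        r2, _ = m2.ranef_conditional(np.zeros((N, p)), np.eye(p), np.eye(p))
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_rank_deficient_design_rejected(self):
        Y = np.zeros((6, 2))
        T = np.ones(6)  # exposure column equals the constant column
        with pytest.raises(MLMEError, match="rank"):
            MultivariateMixedLM(Y, T, None, groups=[0, 0, 1, 1, 2, 2])

    def test_summary_lists_all_outcomes(self, capsys):
        model, _ = _tiny_model(seed=21, n_clusters=6, sibs=2, p=2, n_cov=1)
        res = model.fit(config=GibbsConfig(n_iter=300, burn_in=100, seed=22))
        text = res.summary()
        assert "y0" in text and "y1" in text and "Exposure" in text
        frame = res.summary_frame()
        assert len(frame) == model.n_coef * model.n_outcomes
        diag = res.diagnostics()
        assert (diag["ess"] > 0).all()


class TestJointCorrectness:
    def test_geweke_forward_vs_successive_conditional(self):
        """Forward prior+likelihood simulation and Gibbs-updated
        successive-conditional simulation must share the marginal moments
        of the exposure coefficient and the residual variances."""
        p, sibs, J = 2, 2, 10
        N = J * sibs
        v0, nu0 = 1.0, 4.0
        S0 = np.eye(p)
        groups = np.repeat(np.arange(J), sibs)
        T = np.tile([1.0, 0.0], J)
        Z = np.column_stack([np.ones(N), T])
        M = 3000
        rng = np.random.default_rng(23)

        def forward_draw():
            B = rng.normal(0.0, np.sqrt(v0), (2, p))
            Sb = invwishart.rvs(nu0, S0, random_state=rng)
            Se = invwishart.rvs(nu0, S0, random_state=rng)
            b = rng.multivariate_normal(np.zeros(p), Sb, J)
            eps = rng.multivariate_normal(np.zeros(p), Se, N)
            Y = Z @ B + b[groups] + eps
            return B, Sb, Se, b, Y

        fwd_beta, fwd_se = [], []
        for _ in range(M):
            B, _, Se, _, _ = forward_draw()
            fwd_beta.append(B[1, 0])
            fwd_se.append(np.diag(Se))

        B, Sb, Se, b, Y = forward_draw()
        model = MultivariateMixedLM(Y, T, None, groups)
        gib_beta, gib_se = [], []
        for _ in range(M):
            se_inv, sb_inv = np.linalg.inv(Se), np.linalg.inv(Sb)
            B = model._update_coefficients(b[groups], se_inv, v0, rng)
            fitted = Z @ B
            b = model._update_random_effects(fitted, sb_inv, se_inv, rng)
            Sb = invwishart.rvs(nu0 + J, S0 + b.T @ b, random_state=rng)
            resid = model.endog - fitted - b[groups]
            Se = invwishart.rvs(nu0 + N, S0 + resid.T @ resid, random_state=rng)
            eps = rng.standard_normal((N, p)) @ np.linalg.cholesky(Se).T
            model.endog = fitted + b[groups] + eps  # re-draw the data
            gib_beta.append(B[1, 0])
            gib_se.append(np.diag(Se))

        fwd_beta, gib_beta = np.array(fwd_beta), np.array(gib_beta)
        ess = max(effective_sample_size(gib_beta), 10.0)
        se_mean = np.sqrt(fwd_beta.var() / M + gib_beta.var() / ess)
        assert abs(fwd_beta.mean() - gib_beta.mean()) < 4 * se_mean
        assert 0.7 < gib_beta.var(ddof=1) / fwd_beta.var(ddof=1) < 1.4
        fwd_se, gib_se = np.array(fwd_se), np.array(gib_se)
        # IW(4, I_2) marginal variances have prior mean 1 exactly
        for k in range(p):
            ess_k = max(effective_sample_size(gib_se[:, k]), 10.0)
            tol = 4 * np.sqrt(fwd_se[:, k].var() / M + gib_se[:, k].var() / ess_k)
            assert abs(fwd_se[:, k].mean() - gib_se[:, k].mean()) < tol
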