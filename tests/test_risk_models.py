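import numpy as np
import pytest

from doserr.risk_models import (
    ConvergenceError,
    OutcomeData,
    RiskModelSpec,
    fit_err,
    fit_gaussian_ols,
    fit_null,
    fit_poisson_linear,
    information_matrix,
    log_likelihood,
    m_matrix,
    score_vector,
)

def _expected_loglik_hessian(spec, theta, d, h=1e-5, sigma2=None):
    """Central-difference Hessian of g(t) = E_theta[loglik(t)]: for both
    families E_Y enters linearly, so g(t) is loglik(t) with y replaced by the
    mean under theta."""
    if spec.family == "gaussian_linear":
        zd = np.column_stack([np.ones(d.n), d.dose])
        mean_y = zd @ theta
    else:
        from doserr.risk_models import _mu_grad

        mean_y, _ = _mu_grad(spec, theta, d)
    dm = OutcomeData(y=mean_y, dose=d.dose, offset=d.offset,
                     background=d.background, modifier=d.modifier)

    def g(t):
        return log_likelihood(spec, t, dm, sigma2=sigma2)

    p = len(theta)
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            ei, ej = np.eye(p)[i] * h, np.eye(p)[j] * h
            hess[i, j] = (
                g(theta + ei + ej) - g(theta + ei - ej)
                - g(theta - ei + ej) + g(theta - ei - ej)
            ) / (4 * h * h)
    return -hess


class TestGaussianOLS:
    def test_perfect_fit(self):
        z = np.array([0.0, 1, 2, 3])
        f = fit_gaussian_ols(OutcomeData(y=1 + 2 * z, dose=z))
        np.testing.assert_allclose(f.theta, [1, 2], atol=1e-12)
        assert f.sigma2 == pytest.approx(0, abs=1e-24)

    def test_closed_form_three_points(self):
        f = fit_gaussian_ols(OutcomeData(y=[0, 1, 1], dose=[0, 1, 2]))
        np.testing.assert_allclose(f.theta, [1 / 6, 1 / 2], rtol=1e-12)
        assert f.sigma2 == pytest.approx(1 / 6, rel=1e-12)  # RSS / (n - 2)

    def test_permutation_invariance(self, rng):
        z = rng.uniform(0, 2, 30)
        y = 0.5 + 1.2 * z + rng.normal(0, 0.3, 30)
        f1 = fit_gaussian_ols(OutcomeData(y=y, dose=z))
        perm = rng.permutation(30)
        f2 = fit_gaussian_ols(OutcomeData(y=y[perm], dose=z[perm]))
        np.testing.assert_allclose(f1.theta, f2.theta, rtol=1e-10)
        np.testing.assert_allclose(f1.information, f2.information, rtol=1e-10)
        np.testing.assert_allclose(f1.M[perm], f2.M, rtol=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        z = rng.uniform(0, 3, 50)
        y = 1 + 0.7 * z + rng.normal(0, 0.5, 50)
        f = fit_gaussian_ols(OutcomeData(y=y, dose=z))
        res = sm.OLS(y, sm.add_constant(z)).fit()
        np.testing.assert_allclose(f.theta, res.params, atol=1e-8)
        np.testing.assert_allclose(f.sigma2, res.mse_resid, rtol=1e-10)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_ols(OutcomeData(y=[1.0, 2, 3], dose=[2.0, 2, 2]))


class TestPoissonLinear:
    def test_saturated_two_points(self):
        f = fit_poisson_linear(OutcomeData(y=[1, 3], dose=[0, 1]))
        np.testing.assert_allclose(f.theta, [1, 2], atol=1e-8)

    def test_slope_sign_matches_association(self, rng):
        z = rng.uniform(0, 2, 200)
        y = rng.poisson(1 + 2 * z)
        f = fit_poisson_linear(OutcomeData(y=y, dose=z))
        assert np.sign(f.beta) == np.sign(np.cov(y, z)[0, 1])

    def test_matches_identity_link_glm(self, rng):
        import statsmodels.api as sm

        z = rng.uniform(0, 2, 300)
        y = rng.poisson(1 + 0.5 * z)
        f = fit_poisson_linear(OutcomeData(y=y, dose=z))
        glm = sm.GLM(
            y, sm.add_constant(z),
            family=sm.families.Poisson(link=sm.families.links.Identity()),
        ).fit(tol=1e-12)
        np.testing.assert_allclose(f.theta, glm.params, atol=1e-8)

    def test_recovery_large_n(self):
        rng = np.random.default_rng(321)
        z = rng.uniform(0, 2, 10_000)
        theta = np.array([1.0, 0.5])
        y = rng.poisson(theta[0] + theta[1] * z)
        f = fit_poisson_linear(OutcomeData(y=y, dose=z))
        se = np.sqrt(np.diag(np.linalg.inv(f.information)))
        assert np.all(np.abs(f.theta - theta) < 3 * se)

    def test_all_zero_outcomes_is_boundary_error(self):
        with pytest.raises(ValueError):
            fit_poisson_linear(OutcomeData(y=[0, 0, 0], dose=[0, 1, 2]))

    def test_offset_scales_mean(self, rng):
        z = np.tile(rng.uniform(0.5, 2, 100), 4)
        t = np.full(400, 2.5)
        y = rng.poisson(t * (1 + 0.5 * z))
        f = fit_poisson_linear(OutcomeData(y=y, dose=z, offset=t))
        assert abs(f.theta[0] - 1) < 0.3 and abs(f.beta - 0.5) < 0.2


class TestErr:
    def test_saturated_closed_form(self):
        # mean Y = (2, 6) at Z = (0, 1): exp(a0) = 2, 1 + beta = 3
        f = fit_err(OutcomeData(y=[2, 6], dose=[0, 1]))
        np.testing.assert_allclose(f.theta, [np.log(2), 2.0], atol=1e-8)

    def test_null_data_gives_null_slope(self, rng):
        z = rng.uniform(0, 2, 2000)
        y = rng.poisson(2.0, size=2000)
        f = fit_err(OutcomeData(y=y, dose=z))
        se = np.sqrt(np.diag(np.linalg.inv(f.information)))
        assert abs(f.beta) < 3 * se[-1]
        assert abs(f.theta[0] - np.log(y.mean())) < 3 * se[0]

    def test_recovery_with_covariates(self):
        rng = np.random.default_rng(99)
        n = 10_000
        z = rng.lognormal(-0.5, 0.7, n)
        a = rng.integers(0, 2, n).astype(float)
        c = rng.normal(0, 1, n)
        theta = np.array([-2.0, 0.3, 0.5, 1.5])
        mu = np.exp(theta[0] + theta[1] * a) * (1 + theta[3] * z * np.exp(theta[2] * c))
        y = rng.poisson(mu)
        f = fit_err(OutcomeData(y=y, dose=z, background=a, modifier=c))
        se = np.sqrt(np.diag(np.linalg.inv(f.information)))
        assert np.all(np.abs(f.theta - theta) < 3 * se)

    def test_constant_modifier_rejected(self):
        with pytest.raises(ValueError, match="alpha2"):
            fit_err(
                OutcomeData(y=[1, 2], dose=[0, 1], modifier=[1.0, 1.0]),
                use_modifier=True,
            )


class TestInformationMatrix:
    def test_err_single_record_hand_value(self):
        spec = RiskModelSpec("err_poisson", True, True)
        d = OutcomeData(y=[0], dose=[1], background=[0], modifier=[0])
        contrib = information_matrix(spec, np.zeros(4), d)
        expect = np.zeros((4, 4))
        expect[0, 0] = expect[0, 3] = expect[3, 0] = expect[3, 3] = 1
        np.testing.assert_allclose(contrib, expect)

    @pytest.mark.parametrize(
        "family,theta,kwargs,sigma2",
        [
            ("gaussian_linear", np.array([0.5, 1.2]), {}, 0.8),
            ("poisson_linear", np.array([1.0, 0.7]), {}, None),
            (
                "err_poisson",
                np.array([-0.5, 0.3, 0.2, 0.9]),
                {"background": [0, 1, 0, 1, 1.0], "modifier": [0.2, -0.1, 0, 0.5, 0.3]},
                None,
            ),
        ],
    )
    def test_matches_numerical_expected_hessian(self, family, theta, kwargs, sigma2):
        spec = RiskModelSpec(
            family,
            uses_background_covariates="background" in kwargs,
            uses_modifiers="modifier" in kwargs,
        )
        d = OutcomeData(y=np.zeros(5), dose=[0.1, 0.5, 1.0, 1.5, 2.0], **kwargs)
        info = information_matrix(spec, theta, d, sigma2=sigma2)
        num = _expected_loglik_hessian(spec, theta, d, sigma2=sigma2)
        np.testing.assert_allclose(info, num, rtol=1e-4, atol=1e-7)

    def test_poisson_zero_dose_diagonal(self):
        spec = RiskModelSpec("poisson_linear")
        d = OutcomeData(y=[1, 2, 0], dose=[0.0, 0, 0])
        info = information_matrix(spec, np.array([2.0, 1.0]), d)
        assert info[0, 1] == 0

    def test_symmetric_psd(self, rng):
        spec = RiskModelSpec("err_poisson", True, True)
        for _ in range(5):
            d = OutcomeData(
                y=np.zeros(8), dose=rng.uniform(0, 2, 8),
                background=rng.normal(size=8), modifier=rng.normal(size=8),
            )
            info = information_matrix(spec, np.array([0.1, 0.2, 0.1, 0.5]), d)
            np.testing.assert_allclose(info, info.T, atol=1e-12)
            assert np.linalg.eigvalsh(info).min() > -1e-10

    def test_inadmissible_theta_rejected(self):
        spec = RiskModelSpec("poisson_linear")
        with pytest.raises(ValueError):
            information_matrix(spec, np.array([-1.0, 0.0]), OutcomeData(y=[1], dose=[1]))


class TestMMatrix:
    def test_poisson_hand_row(self):
        m = m_matrix(
            RiskModelSpec("poisson_linear"), np.array([1.0, 1.0]),
            OutcomeData(y=[0], dose=[1]),
        )
        np.testing.assert_allclose(m, [[0.5, 0.5]])

    def test_err_hand_row(self):
        spec = RiskModelSpec("err_poisson", True, True)
        m = m_matrix(spec, np.zeros(4), OutcomeData(y=[0], dose=[2],
                                                    background=[0], modifier=[0]))
        np.testing.assert_allclose(m, [[1, 0, 0, 2]])

    @pytest.mark.parametrize("family", ["gaussian_linear", "poisson_linear", "err_poisson"])
    def test_conditional_score_is_linear_in_true_dose(self, family, rng):
        """E(S_w | X) = c + beta M'X: replacing Y by its conditional mean
        under two different true-dose vectors shifts the score by exactly
        beta M'(X1 - X2)."""
        n = 4
        for _ in range(4):
            z = rng.uniform(0.2, 2, n)
            kwargs, sigma2 = {}, None
            if family == "err_poisson":
                kwargs = {"background": rng.normal(size=n), "modifier": rng.normal(size=n)}
                theta = np.array([0.2, 0.4, 0.3, 0.8])
            elif family == "poisson_linear":
                theta = np.array([1.5, 0.6])
            else:
                theta = np.array([0.5, 0.9])
                sigma2 = 1.7
            spec = RiskModelSpec(family, "background" in kwargs, "modifier" in kwargs)
            beta = theta[-1]
            x1, x2 = rng.uniform(0.1, 2, n), rng.uniform(0.1, 2, n)

            def mean_given(x):
                if family == "gaussian_linear":
                    return theta[0] + beta * x
                if family == "poisson_linear":
                    return theta[0] + beta * x
                a = kwargs["background"]; c = kwargs["modifier"]
                return np.exp(theta[0] + theta[1] * a) * (
                    1 + beta * x * np.exp(theta[2] * c)
                )

            d1 = OutcomeData(y=mean_given(x1), dose=z, **kwargs)
            d2 = OutcomeData(y=mean_given(x2), dose=z, **kwargs)
            s1 = score_vector(spec, theta, d1, sigma2=sigma2)
            s2 = score_vector(spec, theta, d2, sigma2=sigma2)
            m = m_matrix(spec, theta, OutcomeData(y=np.zeros(n), dose=z, **kwargs),
                         sigma2=sigma2)
            np.testing.assert_allclose(s1 - s2, beta * m.T @ (x1 - x2), rtol=1e-9)


class TestScoreUnbiasedness:
    def test_plug_in_score_mean_zero_under_berkson(self):
        """With Y drawn given true X and E(X|W) = Z, the naive score at the
        true parameters averages to zero (within 3 MC SEs, 2000 reps)."""
        from doserr.synthetic import _lognormal_unit_mean

        rng = np.random.default_rng(17)
        n = 50
        z = rng.lognormal(0, 0.6, n)
        gidx = np.concatenate([np.zeros(10, int), np.arange(1, n - 9)])
        theta = np.array([1.0, 0.8])
        spec = RiskModelSpec("poisson_linear")
        reps = 2000
        scores = np.empty((reps, 2))
        for r in range(reps):
            g = _lognormal_unit_mean(rng, 0.5, n - 9)
            u = _lognormal_unit_mean(rng, 0.3, n)
            x = z * g[gidx] * u  # E(X|W) = Z by unit-mean factors
            y = rng.poisson(theta[0] + theta[1] * x)
            d = OutcomeData(y=y.astype(float), dose=z)
            scores[r] = score_vector(spec, theta, d)
        mean = scores.mean(axis=0)
        mc_se = scores.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean) < 3 * mc_se)


class TestNullFit:
    def test_gaussian_null_parameters(self, rng):
        y = rng.normal(2.0, 1.0, 40)
        f = fit_null("gaussian_linear", OutcomeData(y=y, dose=rng.uniform(0, 1, 40)))
        assert f.theta[0] == pytest.approx(y.mean())
        assert f.beta == 0.0
        assert f.sigma2 == pytest.approx(y.var(ddof=1))

    def test_poisson_null_rate(self, rng):
        y = rng.poisson(3.0, 60).astype(float)
        t = np.full(60, 2.0)
        f = fit_null("poisson_linear", OutcomeData(y=y, dose=rng.uniform(0, 1, 60), offset=t))
        assert f.theta[0] == pytest.approx(y.sum() / t.sum())
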