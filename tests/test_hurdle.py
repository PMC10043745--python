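import numpy as np
import pandas as pd
import pytest
from scipy import stats

import planshare as ps
from planshare.design import DesignSpec, build_design
from planshare.errors import ConvergenceError, InvalidInputError
from planshare.hurdle import (
    HurdleFit,
    _truncated_mean,
    _ztnb_obj_grad,
    duan_smearing_factor,
    fit_logistic,
    fit_ztnb,
    marginal_effects,
    ztnb_loglik,
    ztnb_logpmf,
)
from planshare.rng import substream
from planshare.synthetic import sample_ztnb


def bruteforce_zt_loglik(coefs, alpha, y, X):
    """Oracle: truncated pmf built directly from scipy's NB pmf."""
    mu = np.exp(X @ np.asarray(coefs))
    r = 1.0 / alpha
    p = r / (r + mu)
    num = stats.nbinom.pmf(y, r, p)
    denom = 1.0 - stats.nbinom.pmf(0, r, p)
    return float(np.log(num / denom).sum())


def _sim_design(n, seed, two_cols=True):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n)]) if two_cols else np.ones((n, 1))
    return X


class TestZtnbLikelihood:
    def test_truncated_pmf_normalizes(self):
        for mu, alpha in [(0.5, 0.3), (2.0, 0.8), (8.0, 0.1), (1.5, 2.0)]:
            k = np.arange(1, 4000)
            total = np.exp(ztnb_logpmf(k, np.full_like(k, mu, dtype=float), alpha)).sum()
            assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        X = _sim_design(n, seed)
        y = 1 + rng.poisson(rng.uniform(0.5, 3.0), size=n)
        coefs = rng.normal(0, 0.5, size=2)
        alpha = float(rng.uniform(0.05, 1.5))
        assert ztnb_loglik(coefs, alpha, y, X) == pytest.approx(
            bruteforce_zt_loglik(coefs, alpha, y, X), abs=1e-8
        )

    def test_poisson_limit_closed_form(self):
        # y=1, mu=1: zero-truncated Poisson term is -1 - log(1 - e^-1)
        expected = -1.0 - np.log(1.0 - np.exp(-1.0))
        got = ztnb_logpmf(np.array([1.0]), np.array([1.0]), 1e-10)[0]
        assert got == pytest.approx(expected, abs=1e-6)

    def test_poisson_limit_general(self):
        import math

        y = np.arange(1, 8, dtype=float)
        mu = np.full_like(y, 1.7)
        ztp = y * np.log(1.7) - 1.7 - [math.lgamma(k + 1) for k in y]
        ztp = ztp - np.log(1 - np.exp(-1.7))
        assert np.allclose(ztnb_logpmf(y, mu, 1e-9), ztp, atol=1e-6)

    def test_zero_count_rejected(self):
        with pytest.raises(InvalidInputError):
            ztnb_loglik(np.zeros(1), 0.5, np.array([0]), np.ones((1, 1)))

    def test_gradient_matches_numeric(self):
        from scipy.optimize import approx_fprime

        rng = np.random.default_rng(4)
        n = 150
        X = _sim_design(n, 4)
        y = 1 + rng.poisson(1.5, size=n)
        theta = np.array([0.3, -0.2, np.log(0.4)])
        num = approx_fprime(theta, lambda t: _ztnb_obj_grad(t, y, X)[0], 1e-7)
        ana = _ztnb_obj_grad(theta, y, X)[1]
        assert np.allclose(num, ana, rtol=1e-4, atol=1e-4)


class TestZtnbFit:
    def _fit_fixture(self, n=2000, seed=0, alpha=0.4):
        rng = substream(seed, "ztnb-fixture")
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.3, n)])
        beta = np.array([0.5, 0.2, -0.3])
        y = sample_ztnb(np.exp(X @ beta), alpha, rng)
        return X, y.astype(float), beta, alpha

    def test_mle_is_local_maximum(self):
        X, y, *_ = self._fit_fixture()
        b, alpha, _, ll, conv = fit_ztnb(y, X)
        assert conv
        for j in range(len(b)):
            for eps in (1e-3, -1e-3):
                b2 = b.copy()
                b2[j] += eps
                assert ztnb_loglik(b2, alpha, y, X) <= ll + 1e-9

    def test_recovers_planted_parameters(self):
        X, y, beta, alpha = self._fit_fixture(n=8000, seed=1)
        b, a, vcov, _, conv = fit_ztnb(y, X)
        se = np.sqrt(np.diag(vcov))
        assert conv
        assert np.all(np.abs(b - beta) < 3 * se[:-1])
        assert abs(np.log(a) - np.log(alpha)) < 3 * se[-1]

    def test_observed_information_matches_independent_hessian(self):
        X, y, *_ = self._fit_fixture(n=1500, seed=2)
        b, alpha, vcov, _, _ = fit_ztnb(y, X)
        theta = np.concatenate([b, [np.log(alpha)]])

        def ll(t):
            return ztnb_loglik(t[:-1], float(np.exp(t[-1])), y, X)

        k = len(theta)
        H = np.zeros((k, k))
        h = 5e-4
        for i in range(k):  # central second differences of the loglik itself
            for j in range(k):
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[i] += h; tpp[j] += h
                tpm[i] += h; tpm[j] -= h
                tmp[i] -= h; tmp[j] += h
                tmm[i] -= h; tmm[j] -= h
                H[i, j] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * h * h)
        vcov_fd = np.linalg.inv(-(H + H.T) / 2)
        assert np.allclose(
            np.sqrt(np.diag(vcov)), np.sqrt(np.diag(vcov_fd)), rtol=1e-4
        )

    def test_cross_check_statsmodels_truncated_nb(self):
        from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

        X, y, *_ = self._fit_fixture(n=3000, seed=3)
        b, alpha, _, ll, _ = fit_ztnb(y, X)
        theta = np.concatenate([b, [alpha]])
        model = TruncatedLFNegativeBinomialP(y, X, truncation=0, p=2)
        # identical likelihood value at our MLE
        assert model.loglike(theta) == pytest.approx(ll, abs=1e-6)
        # polishing from our MLE moves neither the parameters nor the loglik
        sm_fit = model.fit(start_params=theta, method="bfgs", disp=0)
        assert np.allclose(sm_fit.params, theta, atol=1e-3)
        assert sm_fit.llf <= ll + 1e-6

    def test_truncated_mean_identity_vs_simulation(self):
        rng = substream(9, "mean-identity")
        mu, alpha = 1.8, 0.6
        draws = sample_ztnb(np.full(200000, mu), alpha, rng)
        expected = _truncated_mean(np.array([mu]), alpha)[0]
        mc_se = draws.std() / np.sqrt(len(draws))
        assert draws.mean() == pytest.approx(expected, abs=3 * mc_se)


class TestLogistic:
    def test_degenerate_outcome_raises(self):
        X = np.ones((50, 1))
        with pytest.raises(ConvergenceError):
            fit_logistic(np.ones(50), X)

    def test_separation_raises(self):
        x = np.concatenate([np.zeros(25), np.ones(25)])
        X = np.column_stack([np.ones(50), x])
        with pytest.raises(ConvergenceError):
            fit_logistic(x, X)  # outcome perfectly predicted by x


def _hurdle_cohort(n, seed, params=None):
    rng = substream(seed, "hurdle-cohort")
    cohort = pd.DataFrame(
        {
            "plan_type": rng.choice(
                ["coinsurance", "balanced", "copay", "deductible"], size=n,
                p=[0.134, 0.215, 0.147, 0.504],
            ),
            "age_group": rng.choice(["40-64", "65-74"], size=n, p=[0.95, 0.05]),
            "race_ethnicity": rng.choice(
                ["Asian", "Black", "Hispanic", "White", "Unknown"], size=n,
                p=[0.036, 0.073, 0.071, 0.713, 0.107],
            ),
            "cci_category": rng.choice(["0", "1", "2", "3+"], size=n,
                                       p=[0.874, 0.104, 0.018, 0.004]),
            "region": rng.choice([f"R{i}" for i in range(1, 6)], size=n),
        }
    )
    return ps.generate_outcomes(cohort, params or ps.OutcomeParams.typical(), seed=seed)


class TestFitHurdle:
    def test_parts_fit_on_correct_samples(self):
        data = _hurdle_cohort(12000, seed=0)
        fit = ps.fit_hurdle(data, DesignSpec(plan_ref="coinsurance"))
        assert fit.n_obs_part1 == len(data)
        assert fit.n_obs_part2 == int((data["n_services"] > 0).sum())
        assert fit.alpha > 0
        assert fit.converged_part1 and fit.converged_part2

    def test_vcov_symmetric_psd(self):
        data = _hurdle_cohort(8000, seed=1)
        fit = ps.fit_hurdle(data, DesignSpec(plan_ref="coinsurance"))
        for V in (fit.part1_vcov, fit.part2_vcov):
            V = np.asarray(V)
            assert np.allclose(V, V.T, atol=1e-10)
            assert np.linalg.eigvalsh(V).min() > -1e-10

    def test_all_positive_outcome_rejected(self):
        data = _hurdle_cohort(500, seed=2)
        data["n_services"] = data["n_services"] + 1
        with pytest.raises(ConvergenceError):
            ps.fit_hurdle(data, DesignSpec(plan_ref="coinsurance"))


class TestMarginalEffects:
    def _two_group_fit(self, b1=0.0, alpha=0.5, n=400):
        """Hand-assembled fit: intercept + one plan dummy, everything else flat."""
        data = pd.DataFrame(
            {
                "plan_type": ["coinsurance"] * (n // 2) + ["copay"] * (n // 2),
                "age_group": "40-64",
                "race_ethnicity": "White",
                "cci_category": "0",
                "region": "R1",
                "n_services": 2,
            }
        )
        spec = DesignSpec(plan_ref="coinsurance")
        vcov = np.diag([0.01, 0.02, 0.05])  # (b0, b1, log alpha)
        fit = HurdleFit(
            spec=spec, columns=["intercept", "plan:copay"],
            columns_part2=["intercept", "plan:copay"],
            part1_coefs=np.array([0.0, 0.0]), part1_vcov=np.eye(2),
            part2_coefs=np.array([0.4, b1]), part2_vcov=vcov,
            alpha=alpha, loglik_part1=0.0, loglik_part2=0.0,
            n_obs_part1=n, n_obs_part2=n,
            converged_part1=True, converged_part2=True, smearing_factor=1.0,
        )
        return fit, data, vcov

    def test_null_contrast_has_zero_ame(self):
        fit, data, _ = self._two_group_fit(b1=0.0)
        (eff,) = marginal_effects(fit, data, apply_smearing=False)
        assert eff.estimate == pytest.approx(0.0, abs=1e-12)

    def test_delta_se_matches_closed_form(self):
        fit, data, vcov = self._two_group_fit(b1=-0.3, alpha=0.5)
        (eff,) = marginal_effects(fit, data, apply_smearing=False)
        b0, b1 = fit.part2_coefs
        r = 1.0 / fit.alpha

        def dtm_dmu(mu):
            p0 = (r / (r + mu)) ** r
            return 1.0 / (1 - p0) - mu * p0 * r / ((r + mu) * (1 - p0) ** 2)

        mu0, mu1 = np.exp(b0), np.exp(b0 + b1)
        # d AME/d b0 = tm'(mu1) mu1 - tm'(mu0) mu0 ; d/d b1 = tm'(mu1) mu1
        g0 = dtm_dmu(mu1) * mu1 - dtm_dmu(mu0) * mu0
        g1 = dtm_dmu(mu1) * mu1
        # d/d log alpha: numeric (closed form is unwieldy) — but exclude from
        # the analytic check by zeroing its variance
        vcov_beta_only = vcov.copy()
        vcov_beta_only[2, 2] = 0.0
        fit.part2_vcov = vcov_beta_only
        (eff2,) = marginal_effects(fit, data, apply_smearing=False)
        se_analytic = np.sqrt(
            g0 * g0 * vcov[0, 0] + g1 * g1 * vcov[1, 1]
        )
        assert eff2.se == pytest.approx(float(se_analytic), rel=1e-5)

    def test_ci_brackets_estimate(self):
        fit, data, _ = self._two_group_fit(b1=-0.3)
        (eff,) = marginal_effects(fit, data, apply_smearing=False)
        assert eff.ci_low <= eff.estimate <= eff.ci_high

    def test_smearing_factor_scales_mu(self):
        data = _hurdle_cohort(12000, seed=3)
        fit = ps.fit_hurdle(data, DesignSpec(plan_ref="coinsurance"))
        effects_off = marginal_effects(fit, data, apply_smearing=False)
        effects_on = marginal_effects(fit, data, apply_smearing=True)
        assert effects_on[0].smearing_factor != 1.0
        # smearing rescales, it does not flip signs
        for a, b in zip(effects_off, effects_on):
            assert np.sign(a.estimate) == np.sign(b.estimate) or a.estimate == 0

    def test_planted_negative_effect_detected(self):
        params = ps.OutcomeParams(
            beta_logit={"intercept": -0.5},
            beta_count={"intercept": 0.5, "plan:copay": -0.2},
            alpha=0.3,
        )
        data = _hurdle_cohort(30000, seed=4, params=params)
        fit = ps.fit_hurdle(data, DesignSpec(plan_ref="coinsurance"))
        effects = {e.contrast: e for e in marginal_effects(fit, data, apply_smearing=False)}
        e = effects["copay vs coinsurance"]
        assert e.estimate < 0
        assert e.ci_high < 0

    def test_missing_contrast_rejected(self):
        fit, data, _ = self._two_group_fit()
        with pytest.raises(InvalidInputError):
            marginal_effects(fit, data, contrasts=["deductible"])

    def test_duan_factor_definition(self):
        y = np.array([1.0, 2.0, 4.0])
        mu = np.array([2.0, 2.0, 2.0])
        assert duan_smearing_factor(y, mu) == pytest.approx(np.mean(y / mu))
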