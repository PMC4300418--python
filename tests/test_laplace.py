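"""Laplace marginal likelihood: exactness on linear-Gaussian subjects,
quadrature cross-checks and the per-subject joint likelihood."""

import numpy as np
import pytest
from scipy.special import roots_hermitenorm
from scipy.stats import norm

import copdjm as cj


def _one_subject_dataset(pop, seed=3, active=True):
    arms = (
        [cj.simulate.Arm("salmeterol50", cj.DoseRegimen(50.0), 1.0)]
        if active
        else [cj.simulate.Arm("placebo", cj.DoseRegimen(0.0), 1.0)]
    )
    design = cj.TrialDesign(arms=arms, n_subjects=1, seed=seed)
    return cj.simulate_trial(pop, design, cj.reference_distributions())


class TestLaplaceCore:
    def test_linear_gaussian_toy_is_exact(self):
        # y = eta + eps with omega^2 = sigma^2 = 1 and y = 1:
        # -2LL = ln(4*pi) + 1/2 exactly; the Laplace approximation is exact
        lm, eta = cj.laplace_logmarginal(
            lambda e: norm.logpdf(1.0, e[0], 1.0), [[1.0]]
        )
        assert -2 * lm == pytest.approx(np.log(4 * np.pi) + 0.5, abs=1e-6)
        assert eta[0] == pytest.approx(0.5, abs=1e-6)

    def test_degenerate_prior_recovers_eta_zero_likelihood(self):
        lm, _ = cj.laplace_logmarginal(
            lambda e: norm.logpdf(1.0, e[0], 1.0), [[1e-12]]
        )
        assert lm == pytest.approx(norm.logpdf(1.0, 0.0, 1.0), abs=1e-8)

    def test_two_dimensional_linear_gaussian(self):
        # y = eta1 + eta2 + eps: marginal y ~ N(0, o1 + o2 + s^2)
        o1, o2, s, y = 0.3, 0.5, 0.8, 1.4
        lm, _ = cj.laplace_logmarginal(
            lambda e: norm.logpdf(y, e[0] + e[1], s),
            [[o1, 0.0], [0.0, o2]],
        )
        assert lm == pytest.approx(
            norm.logpdf(y, 0.0, np.sqrt(o1 + o2 + s**2)), abs=1e-6
        )

    def test_batched_matches_scalar(self):
        ys = np.array([0.3, -1.0, 2.2])
        omega = np.array([[0.7]])

        def batched(e):
            return norm.logpdf(ys, e[:, 0], 1.0)

        lm, eta, nfail = cj.batched_laplace(batched, omega, np.zeros((3, 1)))
        assert nfail == 0
        for i, y in enumerate(ys):
            ref, _ = cj.laplace_logmarginal(
                lambda e, y=y: norm.logpdf(y, e[0], 1.0), omega
            )
            assert lm[i] == pytest.approx(ref, abs=1e-9)


class TestLaplaceOnModelSubjects:
    def test_within_tenth_of_adaptive_gauss_hermite(self, plain_pop):
        """Nonlinear one-eta subject: Laplace -2LL vs a 64-point
        mode-centred Gauss-Hermite quadrature oracle."""
        pop = plain_pop.replace(omega={"int_dis": {"int_dis": 0.0625}})
        ds = _one_subject_dataset(pop, seed=3)
        mdl = cj.JointFEV1Model(ds, pop, cj.FitConfig(free=()))
        lm, eta_hat = mdl.marginal_loglik(pop)
        ll_fn = mdl._conditional_loglik_fn(pop)

        om = 0.25
        def joint(e):
            return ll_fn(np.array([[e]]))[0] + norm.logpdf(e, 0.0, om)

        mode = eta_hat[0, 0]
        h = 1e-4
        curv = -(joint(mode + h) + joint(mode - h) - 2 * joint(mode)) / h**2
        s = 1.0 / np.sqrt(curv)
        x, w = roots_hermitenorm(64)
        vals = np.array([joint(mode + s * xi) for xi in x])
        oracle = np.log(s * np.sum(w * np.exp(vals + x**2 / 2)))
        assert -2 * lm[0] == pytest.approx(-2 * oracle, abs=0.1)

    def test_placebo_subject_flat_emax_dimension_is_exact(self, plain_pop):
        """With no exposure the Emax eta integrates out exactly, so adding
        it to omega must not change the marginal."""
        pop1 = plain_pop.replace(omega={"int_dis": {"int_dis": 0.0625}})
        pop2 = plain_pop.replace(
            omega={"int_dis": {"int_dis": 0.0625}, "emax": {"emax": 0.49}}
        )
        ds = _one_subject_dataset(pop1, seed=5, active=False)
        lm1 = cj.laplace_marginal_loglik(ds, pop1)
        lm2 = cj.laplace_marginal_loglik(ds, pop2)
        assert lm1 == pytest.approx(lm2, abs=1e-6)


class TestIndividualJointLoglik:
    def test_single_perfect_observation(self, plain_pop):
        """One observation equal to IPRED contributes -0.5*ln(2*pi*sigma^2);
        the completer term adds ln S(end)."""
        pop = cj.final_model_population(iiv="none", covariates=False).replace(
            tv_slope_dis=0.0
        )
        design = cj.TrialDesign(
            arms=[cj.simulate.Arm("placebo", cj.DoseRegimen(0.0), 1.0)],
            n_subjects=1, duration=4.0, seed=2,
        )
        ds = cj.simulate_trial(
            pop.replace(sigma_add=1e-12, hazard=cj.HazardSpec(beta0=1e-12)),
            design, cj.reference_distributions(),
        )
        ll = cj.individual_joint_loglik(ds, pop, include_dropout=False)
        n_obs = 2  # baseline + week 4
        assert ll == pytest.approx(-0.5 * n_obs * np.log(2 * np.pi * 0.13**2))
        ll_joint = cj.individual_joint_loglik(ds, pop, include_dropout=True)
        h = 0.006 * np.exp(-0.88 * float(ds.df.DV.iloc[0]))
        assert ll_joint - ll == pytest.approx(-h * 4.0, rel=1e-9)

    def test_doubling_sigma_costs_log_two_per_perfect_obs(self, plain_pop):
        pop = cj.final_model_population(iiv="none", covariates=False).replace(
            tv_slope_dis=0.0
        )
        design = cj.TrialDesign(
            arms=[cj.simulate.Arm("placebo", cj.DoseRegimen(0.0), 1.0)],
            n_subjects=1, duration=4.0, seed=2,
        )
        ds = cj.simulate_trial(
            pop.replace(sigma_add=1e-12, hazard=cj.HazardSpec(beta0=1e-12)),
            design, cj.reference_distributions(),
        )
        ll1 = cj.individual_joint_loglik(ds, pop, include_dropout=False)
        ll2 = cj.individual_joint_loglik(
            ds, pop.replace(sigma_add=0.26), include_dropout=False
        )
        assert ll1 - ll2 == pytest.approx(2 * np.log(2.0))

    def test_zero_residual_variance_rejected(self, plain_pop):
        pop = cj.final_model_population(iiv="none", covariates=False).replace(
            sigma_add=0.0
        )
        design = cj.TrialDesign(
            arms=[cj.simulate.Arm("placebo", cj.DoseRegimen(0.0), 1.0)],
            n_subjects=1, duration=4.0, seed=2,
        )
        ds = cj.simulate_trial(
            pop.replace(sigma_add=0.1), design, cj.reference_distributions()
        )
        with pytest.raises(ValueError, match="residual"):
            cj.individual_joint_loglik(ds, pop)


class TestPriorPenalty:
    def test_minimum_at_prior_mean(self):
        prior = cj.PriorSpec()
        pop = cj.final_model_population()
        at_mean = cj.prior_penalty(
            {"tv_emax": 0.78, "ratio_edk50_emax": 4.0 / 0.78}, pop, prior
        )
        for emax in (0.5, 0.78, 1.1):
            for ratio in (3.0, 5.128, 9.0):
                pen = cj.prior_penalty(
                    {"tv_emax": emax, "ratio_edk50_emax": ratio}, pop, prior
                )
                assert pen >= at_mean - 1e-9

    def test_penalty_difference_is_mahalanobis(self):
        prior = cj.PriorSpec()
        pop = cj.final_model_population()
        cov = prior.theta_covariance()
        mu = np.array([0.78, 4.0 / 0.78])

        def maha(x):
            d = np.asarray(x) - mu
            return float(d @ np.linalg.inv(cov) @ d)

        a, b = (0.5, 6.0), (1.0, 4.5)
        pen_a = cj.prior_penalty(
            {"tv_emax": a[0], "ratio_edk50_emax": a[1]}, pop, prior
        )
        pen_b = cj.prior_penalty(
            {"tv_emax": b[0], "ratio_edk50_emax": b[1]}, pop, prior
        )
        assert pen_a - pen_b == pytest.approx(maha(a) - maha(b), rel=1e-9)

    def test_default_degrees_of_freedom_from_historical_study(self):
        assert cj.PriorSpec().df == 24

    def test_omega_block_subsetting(self):
        """A model that dropped IIV on EDK50 gets the 1x1 Emax sub-block."""
        prior = cj.PriorSpec()
        pop = cj.final_model_population()  # IIV on int_dis and emax only
        pen = cj.prior_penalty({}, pop, prior)
        from scipy.stats import invwishart

        expect = -2.0 * invwishart.logpdf(0.49, df=24, scale=0.24)
        assert pen == pytest.approx(expect, rel=1e-9)
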