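"""Structural model: disease status, KPD exposure, Emax effect, covariate
and IIV submodels, trajectory solver and residual error."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import copdjm as cj
from copdjm.structural import solve_fev1_grid

from conftest import make_indiv


class TestDiseaseStatus:
    @pytest.mark.parametrize(
        "t,int_dis,slope,expected",
        [
            (0.0, 1.16, -1e-4, 1.16),
            (84.0, 1.16, -1e-4, 1.1516),
            (30.0, 1.0, 0.0, 1.0),
        ],
    )
    def test_linear_decline(self, t, int_dis, slope, expected):
        assert cj.disease_status(t, int_dis, slope) == pytest.approx(expected)

    def test_rejects_nonpositive_status_and_negative_time(self):
        with pytest.raises(ValueError):
            cj.disease_status(10.0, 0.5, -0.1)
        with pytest.raises(ValueError):
            cj.disease_status(-1.0, 1.0, 0.0)


class TestExposure:
    def test_single_dose_at_time_zero_equals_dose(self):
        reg = cj.DoseRegimen(50.0, interval=12.0, end_time=0.0)
        assert cj.exposure(0.0, reg, 1.0, "a")[0] == pytest.approx(50.0)

    def test_bid_steady_state_trough_with_12h_halflife(self):
        # closed form: Dose*e^(-kde*tau)/(1 - e^(-kde*tau)) = Dose at kde*tau = ln 2
        reg = cj.DoseRegimen(50.0, interval=12.0)
        kde = np.log(2.0) / 0.5
        trough = cj.exposure(np.array([28.0]), reg, kde, "a", predose=True)
        assert trough[0] == pytest.approx(50.0, rel=1e-9)

    @pytest.mark.parametrize("par", ["a", "b", "c"])
    def test_placebo_is_zero(self, par):
        reg = cj.DoseRegimen(0.0)
        assert cj.exposure(np.array([0.0, 5.0, 28.0]), reg, 1.0, par).max() == 0.0

    def test_dose_parameterisation_is_constant_while_active(self):
        reg = cj.DoseRegimen(50.0, interval=12.0, end_time=84.0)
        a = cj.exposure(np.array([0.0, 10.0, 84.0, 90.0]), reg, 1.0, "b",
                        predose=True)
        assert a.tolist() == [0.0, 50.0, 50.0, 0.0]

    def test_input_rate_parameterisation_scales_by_kde(self):
        reg = cj.DoseRegimen(50.0, interval=12.0)
        t = np.array([7.0, 28.0])
        np.testing.assert_allclose(
            cj.exposure(t, reg, 0.7, "c", predose=True),
            0.7 * cj.exposure(t, reg, 0.7, "a", predose=True),
        )

    def test_superposition_matches_explicit_sum(self):
        reg = cj.DoseRegimen(50.0, interval=12.0)
        kde, t = 1.3, 10.25
        doses = np.arange(0.0, t, 0.5)
        doses = doses[doses < t]
        explicit = 50.0 * np.exp(-kde * (t - doses)).sum()
        assert cj.exposure(np.array([t]), reg, kde, "a", predose=True)[0] == (
            pytest.approx(explicit, rel=1e-12)
        )

    def test_invalid_arguments(self):
        reg = cj.DoseRegimen(50.0)
        with pytest.raises(ValueError):
            cj.exposure(1.0, reg, -1.0)
        with pytest.raises(ValueError):
            cj.exposure(1.0, reg, 1.0, "x")


class TestDrugEffect:
    def test_no_exposure_no_effect(self):
        assert cj.drug_effect(0.0, 0.36, 3.1176) == 0.0

    def test_saturates_at_emax(self):
        assert cj.drug_effect(1e12, 0.36, 3.1176) == pytest.approx(0.36, rel=1e-9)

    def test_final_model_value_at_dose_level(self):
        # Emax 0.36, EDK50 = 0.36 * 8.66; multiplier on Kin is 1 + effect
        eff = cj.drug_effect(50.0, 0.36, 0.36 * 8.66)
        assert eff == pytest.approx(0.33887, abs=1e-5)

    @given(
        a=st.floats(0.0, 100.0),
        delta=st.floats(0.01, 100.0),
        emax=st.floats(0.05, 5.0),
        edk50=st.floats(0.1, 100.0),
    )
    def test_strictly_increasing_and_bounded(self, a, delta, emax, edk50):
        lo = cj.drug_effect(a, emax, edk50)
        hi = cj.drug_effect(a + delta, emax, edk50)
        assert hi > lo
        assert hi < emax


class TestCovariateModel:
    def test_reference_subject_reproduces_raw_typicals(
        self, final_pop, reference_covariates
    ):
        tv = cj.apply_covariates(final_pop, reference_covariates)
        assert tv["int_dis"] == pytest.approx(1.16)
        assert tv["emax"] == pytest.approx(0.36)
        assert tv["kin"] == pytest.approx(0.116)

    def test_male_severe_pics_tall_baseline(self, final_pop):
        cov = cj.CovariateVector(
            age=60.0, sex="male", height=180.0, weight=80.0, bmi=24.7,
            severity="severe", reversibility="no", pics="yes",
        )
        tv = cj.apply_covariates(final_pop, cov)
        assert tv["int_dis"] == pytest.approx(
            1.16 * 0.82 * 0.62 * 0.92 * (180 / 170) ** 1.90, rel=1e-9
        )
        assert tv["int_dis"] == pytest.approx(0.60481, abs=1e-5)

    def test_severe_reversible_emax(self, final_pop):
        cov = cj.CovariateVector(
            age=60.0, sex="female", height=170.0, weight=75.0, bmi=26.0,
            severity="severe", reversibility="yes", pics="no",
        )
        tv = cj.apply_covariates(final_pop, cov)
        assert tv["emax"] == pytest.approx(0.36 * 0.94 * 1.05, rel=1e-12)

    def test_power_effect_requires_positive_value(self):
        with pytest.raises(ValueError):
            cj.CovariateEffect("height", "int_dis", "power", 1.9, reference_value=0.0)


class TestApplyIIV:
    def test_zero_etas_identity(self, plain_pop, reference_covariates):
        tv = cj.apply_covariates(plain_pop, reference_covariates)
        ind = cj.apply_iiv(tv, {})
        assert ind.int_dis_i == tv["int_dis"]
        assert ind.emax_i == tv["emax"]

    def test_exp_link_doubles(self, plain_pop, reference_covariates):
        tv = cj.apply_covariates(plain_pop, reference_covariates)
        ind = cj.apply_iiv(tv, {"int_dis": np.log(2.0)})
        assert ind.int_dis_i == pytest.approx(2.32)

    def test_eta_without_variance_is_flagged(self, plain_pop, reference_covariates):
        tv = cj.apply_covariates(plain_pop, reference_covariates)
        with pytest.raises(ValueError, match="no IIV"):
            cj.apply_iiv(tv, {"kin": 0.1}, omega=plain_pop.omega)

    def test_cv_percent_convention(self):
        # omega^2 = 0.0625 is reported as CV 25%
        assert 100 * np.sqrt(0.0625) == pytest.approx(25.0)

    def test_empirical_log_sd_matches_omega(self):
        rng = np.random.default_rng(42)
        omega = 0.25
        draws = rng.normal(0.0, omega, size=100_000)
        vals = 1.16 * np.exp(draws)
        sd = np.log(vals).std(ddof=1)
        se = omega / np.sqrt(2 * (len(draws) - 1))
        assert abs(sd - omega) < 3 * se


class TestSolveFev1:
    def test_placebo_steady_state_is_flat(self):
        ind = make_indiv(slope_dis_i=0.0, emax_i=0.0)
        pts = cj.solve_fev1(ind, cj.DoseRegimen(0.0), np.arange(0, 169, 28.0))
        ipred = np.array([p.ipred for p in pts])
        np.testing.assert_allclose(ipred, 1.16, rtol=1e-12)

    def test_constant_coefficient_closed_form_oracle(self):
        # zero slope: F(t) = Kin'/k + (F0 - Kin'/k) e^(-kt), k = Kin/Dis
        ind = make_indiv(slope_dis_i=0.0)
        reg = cj.DoseRegimen(50.0, interval=12.0)
        times = np.arange(0, 85, 28.0)
        pts = cj.solve_fev1(ind, reg, times)
        a = cj.exposure(times, reg, ind.kde_i, "a", predose=True)
        eff = cj.drug_effect(a, ind.emax_i, ind.edk50_i)
        k = ind.kin_i / ind.int_dis_i
        f = ind.int_dis_i
        for j in range(1, len(times)):
            fss = ind.int_dis_i * (1.0 + eff[j])
            f = fss + (f - fss) * np.exp(-k * (times[j] - times[j - 1]))
            assert pts[j].ipred == pytest.approx(f, abs=1e-10)

    def test_long_run_asymptote_multiplicative_kin(self):
        ind = make_indiv(slope_dis_i=0.0)
        reg = cj.DoseRegimen(50.0, interval=12.0)
        pts = cj.solve_fev1(ind, reg, np.array([0.0, 800.0]))
        a = cj.exposure(np.array([800.0]), reg, ind.kde_i, "a", predose=True)[0]
        limit = ind.int_dis_i * (1.0 + cj.drug_effect(a, ind.emax_i, ind.edk50_i))
        assert pts[-1].ipred == pytest.approx(limit, rel=1e-9)

    def test_closed_form_vs_numeric_on_random_draws(self):
        rng = np.random.default_rng(2024)
        times = np.arange(0, 169, 28.0)
        worst = 0.0
        for _ in range(100):
            ind = make_indiv(
                kin_i=rng.uniform(0.02, 0.4),
                int_dis_i=rng.uniform(0.5, 2.5),
                slope_dis_i=rng.uniform(-3e-4, 1e-4),
                emax_i=rng.uniform(0.0, 1.5),
                edk50_i=rng.uniform(0.5, 20.0),
                kde_i=rng.uniform(0.3, 3.0),
            )
            reg = cj.DoseRegimen(rng.choice([0.0, 50.0]), interval=12.0)
            cf = cj.solve_fev1(ind, reg, times, method="closed_form")
            nm = cj.solve_fev1(ind, reg, times, method="numeric")
            worst = max(worst, max(abs(x.ipred - y.ipred) for x, y in zip(cf, nm)))
        assert worst <= 1e-6

    def test_grid_solver_matches_scalar_path(self):
        ind = make_indiv()
        reg = cj.DoseRegimen(50.0, interval=12.0)
        times = np.arange(0, 169, 28.0)
        pts = cj.solve_fev1(ind, reg, times)
        a = cj.exposure(times, reg, ind.kde_i, "a", predose=True)
        eff = cj.drug_effect(a, ind.emax_i, ind.edk50_i)
        grid = solve_fev1_grid(
            times,
            np.array([ind.int_dis_i]),
            np.array([ind.slope_dis_i]),
            np.array([ind.kin_i]),
            eff[None, :],
        )[0]
        np.testing.assert_allclose([p.ipred for p in pts], grid, rtol=1e-12)

    def test_trajectory_frame_columns(self):
        pts = cj.solve_fev1(make_indiv(), cj.DoseRegimen(0.0), np.array([0.0, 28.0]))
        frame = cj.trajectory_frame(pts, subject_id=7)
        assert list(frame.columns) == ["ID", "TIME", "DIS", "A", "KOUT", "IPRED"]
        assert (frame.ID == 7).all()

    def test_nonpositive_disease_status_raises(self):
        ind = make_indiv(int_dis_i=0.05, slope_dis_i=-1e-3)
        with pytest.raises(ValueError):
            cj.solve_fev1(ind, cj.DoseRegimen(0.0), np.array([0.0, 168.0]))


class TestResidualError:
    def test_zero_eps_identity(self):
        assert cj.residual_error(1.3, 0.13, 0.0, 0.0) == 1.3

    def test_additive_shift(self):
        assert cj.residual_error(1.3, 0.13, 0.0, 1.0) == pytest.approx(1.43)

    def test_combined_nests_additive(self):
        eps = np.array([0.7, -0.4])
        combined = cj.residual_error(1.3, 0.13, 0.0, eps, model="combined")
        additive = cj.residual_error(1.3, 0.13, 0.0, eps[1], model="additive")
        assert combined == pytest.approx(additive)

    def test_proportional_model(self):
        assert cj.residual_error(2.0, 0.0, 0.1, 0.5, model="proportional") == (
            pytest.approx(2.1)
        )

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            cj.residual_error(1.0, -0.1, 0.0, 0.0)
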