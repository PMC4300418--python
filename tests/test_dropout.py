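"""Dropout hazard, survivor, interval probabilities and time sampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import copdjm as cj

from conftest import constant_path

H_FINAL = 0.006 * np.exp(-0.88 * 1.16)  # 0.0021616 per week at IPRED 1.16


class TestHazard:
    def test_constant_baseline(self):
        spec = cj.HazardSpec(beta0=0.006)
        assert cj.hazard(3.0, spec, ipred=0.0) == pytest.approx(0.006)

    def test_informative_term_at_typical_fev1(self):
        spec = cj.HazardSpec(beta0=0.006, beta2=-0.88)
        assert cj.hazard(0.0, spec, ipred=1.16) == pytest.approx(0.0021616, abs=1e-6)

    def test_weibull_shape_one_equals_constant(self):
        w = cj.HazardSpec(form="weibull", beta0=0.01, shape=1.0)
        c = cj.HazardSpec(form="constant", beta0=0.01)
        for t in (0.5, 2.0, 20.0):
            assert cj.hazard(t, w, ipred=1.0) == pytest.approx(
                cj.hazard(t, c, ipred=1.0)
            )

    def test_observed_fev1_required_with_beta1(self):
        spec = cj.HazardSpec(beta0=0.006, beta1=-0.5)
        with pytest.raises(ValueError, match="fev1_obs"):
            cj.hazard(1.0, spec, ipred=1.0)


class TestCumulativeHazardAndSurvivor:
    def test_constant_closed_form(self):
        spec = cj.HazardSpec(beta0=0.006, beta2=-0.88)
        ch = cj.cumulative_hazard(0.0, 24.0, spec, constant_path(1.16))
        assert ch == pytest.approx(H_FINAL * 24.0, rel=1e-8)
        assert ch == pytest.approx(0.051879, abs=1e-5)

    def test_degenerate_interval_is_zero(self):
        spec = cj.HazardSpec(beta0=0.006)
        assert cj.cumulative_hazard(5.0, 5.0, spec, constant_path(1.0)) == 0.0

    def test_piecewise_closed_form_matches_quadrature(self):
        spec = cj.HazardSpec(beta0=0.01, beta2=-0.5)
        grid = np.array([0.0, 4.0, 8.0, 16.0, 24.0])
        ipred = np.array([1.2, 1.1, 1.35, 0.9, 0.9])

        def path(t):
            k = np.searchsorted(grid, t, side="right") - 1
            return ipred[np.clip(k, 0, len(grid) - 2)]

        h_exact = cj.dropout.piecewise_cumulative_hazard(grid, ipred, spec)
        h_quad = sum(
            quad(lambda t: cj.hazard(t, spec, ipred=path(t)), a, b)[0]
            for a, b in zip(grid[:-1], grid[1:])
        )
        assert h_exact[-1] == pytest.approx(h_quad, abs=1e-10)

    def test_survivor_identities(self):
        spec = cj.HazardSpec(beta0=0.006, beta2=-0.88)
        path = constant_path(1.16)
        assert cj.survivor(0.0, spec, path) == 1.0
        assert cj.survivor(24.0, spec, path) == pytest.approx(0.94944, abs=1e-5)
        doubled = cj.HazardSpec(beta0=0.012, beta2=-0.88)
        assert cj.survivor(24.0, doubled, path) == pytest.approx(
            cj.survivor(24.0, spec, path) ** 2, rel=1e-8
        )

    @given(
        beta0=st.floats(1e-4, 0.2),
        beta2=st.floats(-2.0, 0.5),
        ipred=st.floats(0.0, 3.0),
        t1=st.floats(0.1, 30.0),
        t2=st.floats(0.1, 30.0),
    )
    def test_survivor_bounded_and_nonincreasing(self, beta0, beta2, ipred, t1, t2):
        spec = cj.HazardSpec(beta0=beta0, beta2=beta2)
        path = constant_path(ipred)
        lo, hi = sorted([t1, t2])
        s_lo, s_hi = cj.survivor(lo, spec, path), cj.survivor(hi, spec, path)
        assert 0.0 <= s_hi <= s_lo <= 1.0


class TestDropoutPdf:
    def test_at_time_zero_equals_hazard(self):
        spec = cj.HazardSpec(beta0=0.006, beta2=-0.88)
        path = constant_path(1.16)
        assert cj.dropout_pdf(0.0, spec, path) == pytest.approx(H_FINAL, rel=1e-9)

    def test_integrates_to_one_minus_survivor(self):
        spec = cj.HazardSpec(beta0=0.02, beta2=-0.6)
        path = constant_path(1.1)
        total, _ = quad(lambda t: cj.dropout_pdf(t, spec, path), 0.0, 24.0,
                        limit=200)
        assert total == pytest.approx(1.0 - cj.survivor(24.0, spec, path), abs=1e-8)

    def test_pdf_over_survivor_equals_hazard(self):
        spec = cj.HazardSpec(beta0=0.03, beta2=-0.4)
        path = constant_path(0.9)
        for t in (0.0, 3.5, 12.0, 23.0):
            ratio = cj.dropout_pdf(t, spec, path) / cj.survivor(t, spec, path)
            assert ratio == pytest.approx(
                cj.hazard(t, spec, ipred=0.9), abs=1e-10
            )


class TestIntervalProbability:
    def test_simple_subtraction(self):
        spec = cj.HazardSpec(beta0=0.006, beta2=-0.88)
        rec = cj.DropoutRecord(1, 8.0, 12.0, "dropped")
        path = constant_path(1.16)
        expected = cj.survivor(8.0, spec, path) - cj.survivor(12.0, spec, path)
        assert cj.interval_dropout_probability(rec, spec, path) == pytest.approx(
            expected
        )
        assert expected > 0.0

    def test_completer_carries_survivor_at_end(self):
        spec = cj.HazardSpec(beta0=0.006, beta2=-0.88)
        rec = cj.DropoutRecord(1, 24.0, 24.0, "completed")
        assert cj.interval_dropout_probability(
            rec, spec, constant_path(1.16)
        ) == pytest.approx(0.94944, abs=1e-5)

    def test_zero_hazard_limit(self):
        spec = cj.HazardSpec(beta0=1e-300)
        rec = cj.DropoutRecord(1, 8.0, 12.0, "dropped")
        assert cj.interval_dropout_probability(
            rec, spec, constant_path(1.0)
        ) == pytest.approx(0.0, abs=1e-12)


class TestSampleDropoutTime:
    GRID = np.arange(0.0, 25.0, 4.0)

    def test_inverse_cdf_under_constant_hazard(self):
        # a uniform draw u gives t = -ln(u)/h; u = exp(-10 h) -> t = 10
        h = H_FINAL
        spec = cj.HazardSpec(beta0=0.006, beta2=-0.88)

        class FixedRng:
            def uniform(self, size=None):
                return np.full(size, np.exp(-h * 10.0))

        ipred = np.full((1, len(self.GRID)), 1.16)
        t = cj.sample_dropout_time(spec, self.GRID, ipred, 24.0, FixedRng())
        assert t[0] == pytest.approx(10.0, rel=1e-9)

    def test_negligible_hazard_never_drops(self):
        spec = cj.HazardSpec(beta0=1e-300)
        ipred = np.full((50, len(self.GRID)), 1.0)
        t = cj.sample_dropout_time(
            spec, self.GRID, ipred, 24.0, np.random.default_rng(0)
        )
        assert np.all(np.isinf(t))

    def test_empirical_dropout_fraction(self):
        spec = cj.HazardSpec(beta0=0.006, beta2=-0.88)
        n = 100_000
        ipred = np.full((n, len(self.GRID)), 1.16)
        t = cj.sample_dropout_time(
            spec, self.GRID, ipred, 24.0, np.random.default_rng(7)
        )
        frac = np.isfinite(t).mean()
        expect = 1.0 - np.exp(-H_FINAL * 24.0)  # 0.05056
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) < 4 * se

    def test_reproducible_under_fixed_seed(self):
        spec = cj.HazardSpec(beta0=0.05)
        ipred = np.full((100, len(self.GRID)), 1.0)
        t1 = cj.sample_dropout_time(spec, self.GRID, ipred, 24.0,
                                    np.random.default_rng(3))
        t2 = cj.sample_dropout_time(spec, self.GRID, ipred, 24.0,
                                    np.random.default_rng(3))
        np.testing.assert_array_equal(t1, t2)


def test_informative_hazard_selects_low_ipred_subjects():
    """beta2 < 0 makes low-trajectory subjects drop out more often."""
    rng = np.random.default_rng(5)
    n = 20_000
    grid = np.arange(0.0, 25.0, 4.0)
    levels = np.exp(rng.normal(np.log(1.16), 0.25, size=n))
    ipred = np.tile(levels[:, None], (1, len(grid)))
    spec = cj.HazardSpec(beta0=0.03, beta2=-0.88)
    t = cj.sample_dropout_time(spec, grid, ipred, 24.0, rng)
    dropped = np.isfinite(t)
    q1 = levels <= np.quantile(levels, 0.25)
    q4 = levels >= np.quantile(levels, 0.75)
    p1, p4 = dropped[q1].mean(), dropped[q4].mean()
    se = np.sqrt(p1 * (1 - p1) / q1.sum() + p4 * (1 - p4) / q4.sum())
    assert (p1 - p4) / se > 2.33  # one-sided z test at alpha = 0.01
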