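"""Standard-addition linearization, regression and mass-fraction recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idmsquant import (
    AdditionBlend,
    AdditionSeries,
    DomainError,
    IsotopicConstants,
    SingularDesignError,
    UncertainQuantity,
    fit_addition,
    linearize,
    linearize_general,
    matching_report,
    msa_mass_fraction,
    quantify,
)


def _uq(v, u=0.0):
    return UncertainQuantity(v, u)


def _series(rows, w_z=1.0, iso=None):
    blends = [
        AdditionBlend(str(i + 1), _uq(mx), _uq(my), _uq(mz), _uq(r))
        for i, (mx, my, mz, r) in enumerate(rows)
    ]
    return AdditionSeries(blends, w_Z=_uq(w_z), isotopic_constants=iso)


class TestLinearize:
    def test_pt_sample_binary_blend(self, pt_sample_series):
        """First (binary) blend of the PT matrix series maps to x = 0 and
        y = (m_y/m_x) * r = 2.0687."""
        x, y = linearize(pt_sample_series)[0]
        assert x == 0.0
        assert y == pytest.approx(99.340 / 500.770 * 10.428, rel=1e-12)
        assert y == pytest.approx(2.0687, abs=1e-4)

    def test_matched_binary_blend_maps_to_unity(self):
        series = _series([(50, 50, 0, 1.0), (50, 100, 50, 1.0)])
        assert linearize(series)[0] == (0.0, 1.0)

    def test_cya_solution_second_blend(self, cya_solution_series):
        """Hand evaluation of the linearization for a ternary blend; the
        y ordinate carries the stored A1/A2 ratio multiplicatively (the
        inverted-ratio convention lives inside the linearization)."""
        x, y = linearize(cya_solution_series)[1]
        assert x == pytest.approx(48.900 / 48.218, rel=1e-12)
        assert x == pytest.approx(1.01414, abs=5e-6)
        assert y == pytest.approx(98.725 / 48.218 * 1.048, rel=1e-12)
        assert y == pytest.approx(2.14575, abs=5e-6)

    def test_nonpositive_ratio_rejected(self):
        from idmsquant.msa import linearize_values

        with pytest.raises(DomainError):
            linearize_values([(50.0, 50.0, 0.0, -1.0)])


class TestLinearizeGeneral:
    def test_reduces_to_simplified_form_without_overlap(self, cya_solution_series):
        simplified = linearize(cya_solution_series)
        general = linearize_general(cya_solution_series)
        for (x1, y1), (x2, y2) in zip(simplified, general):
            assert x1 == x2
            assert y1 == pytest.approx(y2, rel=1e-14)

    def test_spike_overlap_matches_symbolic_evaluation(self, mel_solution_series):
        """With 1% analyte in the spike, the ordinate follows the general
        overlap expression; checked against an independent sympy build."""
        sympy = pytest.importorskip("sympy")
        m_y, m_x, R_b, xy1, xy2, xx1, xx2 = sympy.symbols(
            "m_y m_x R_b xy1 xy2 xx1 xx2", positive=True
        )
        expr = (m_y / m_x) * (xy2 - R_b * xy1) / (R_b * xx1 - xx2)
        iso = IsotopicConstants(x_y1=0.01, x_x2=0.0, x_x1=1.0, x_y2=1.0)
        series = AdditionSeries(
            mel_solution_series.blends, mel_solution_series.w_Z, iso
        )
        for blend, (x, y) in zip(series.blends, linearize_general(series)):
            expected = float(
                expr.subs(
                    {
                        m_y: blend.m_y.value,
                        m_x: blend.m_x.value,
                        R_b: 1.0 / blend.r_obs.value,
                        xy1: 0.01,
                        xy2: 1.0,
                        xx1: 1.0,
                        xx2: 0.0,
                    }
                )
            )
            assert y == pytest.approx(expected, rel=1e-12)
            assert x == blend.m_z.value / blend.m_x.value

    def test_degenerate_denominator_is_domain_error(self, mel_solution_series):
        iso = IsotopicConstants(x_x1=0.0, x_x2=0.0)
        series = AdditionSeries(
            mel_solution_series.blends, mel_solution_series.w_Z, iso
        )
        with pytest.raises(DomainError, match="overlap"):
            linearize_general(series)


class TestFitAddition:
    def test_pt_sample_regression(self, pt_sample_series):
        """The PT matrix series reproduces the published intercept/slope."""
        fit = fit_addition(linearize(pt_sample_series))
        assert fit.a0 == pytest.approx(2.0534, abs=0.001)
        assert fit.a1 == pytest.approx(1.620, abs=0.002)

    def test_two_point_exact_line(self):
        fit = fit_addition([(0.0, 1.0), (1.0, 2.0)])
        assert fit.a0 == pytest.approx(1.0)
        assert fit.a1 == pytest.approx(1.0)
        assert fit.residuals == pytest.approx((0.0, 0.0), abs=1e-14)
        assert fit.r2 == pytest.approx(1.0)

    @given(data=st.data(), n=st.integers(3, 12))
    @settings(max_examples=30, derandomize=True)
    def test_matches_normal_equations_oracle(self, data, n):
        """Coefficients, errors and covariance against a brute-force
        normal-equations solve."""
        xs = data.draw(
            st.lists(st.floats(0, 10), min_size=n, max_size=n, unique=True)
        )
        ys = data.draw(st.lists(st.floats(-5, 5), min_size=n, max_size=n))
        fit = fit_addition(list(zip(xs, ys)))
        A = np.vstack([np.ones(n), xs]).T
        beta = np.linalg.solve(A.T @ A, A.T @ np.array(ys))
        assert fit.a0 == pytest.approx(beta[0], rel=1e-9, abs=1e-9)
        assert fit.a1 == pytest.approx(beta[1], rel=1e-9, abs=1e-9)
        resid = np.array(ys) - A @ beta
        s2 = (resid @ resid) / (n - 2)
        cov = s2 * np.linalg.inv(A.T @ A)
        assert fit.se_a0 == pytest.approx(np.sqrt(cov[0, 0]), rel=1e-8, abs=1e-12)
        assert fit.se_a1 == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-8, abs=1e-12)
        assert fit.cov_a0a1 == pytest.approx(cov[0, 1], rel=1e-8, abs=1e-12)

    def test_matches_statsmodels(self, pt_sample_series):
        sm = pytest.importorskip("statsmodels.api")
        points = linearize(pt_sample_series)
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        res = sm.OLS(y, sm.add_constant(x)).fit()
        fit = fit_addition(points)
        assert fit.a0 == pytest.approx(res.params[0], rel=1e-10)
        assert fit.a1 == pytest.approx(res.params[1], rel=1e-10)
        assert fit.se_a0 == pytest.approx(res.bse[0], rel=1e-8)
        assert fit.se_a1 == pytest.approx(res.bse[1], rel=1e-8)
        assert fit.r2 == pytest.approx(res.rsquared, rel=1e-10)

    def test_unweighted_residuals_sum_to_zero(self, mel_solution_series):
        fit = fit_addition(linearize(mel_solution_series))
        total_abs = sum(abs(y) for _, y in fit.points)
        assert abs(sum(fit.residuals)) < 1e-9 * total_abs

    def test_identical_x_is_singular(self):
        with pytest.raises(SingularDesignError):
            fit_addition([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])


class TestMassFraction:
    def test_pt_sample_content(self, pt_sample_series):
        """Slope and intercept of the PT series with w_Z = 10.08 mg/kg give
        ~12.8 mg/kg melamine."""
        fit, w_x = quantify(pt_sample_series)
        assert w_x == pytest.approx(12.8, abs=0.05)

    def test_equal_slope_and_intercept_return_w_z(self):
        unit = fit_addition([(0.0, 1.0), (1.0, 2.0)])  # a0 = a1 = 1
        assert msa_mass_fraction(unit, _uq(9.5)) == pytest.approx(9.5)

    def test_mel_solution_target_value(self, mel_solution_series):
        fit, _ = quantify(mel_solution_series)
        assert fit.ratio == pytest.approx(1.004, abs=5e-4)

    @given(f=st.floats(0.2, 5.0))
    @settings(max_examples=30, derandomize=True)
    def test_instrument_bias_cancels_in_ratio(self, f, cya_solution_series):
        """Scaling every observed ratio by a common factor scales a0 and a1
        by f each and leaves a0/a1 unchanged."""
        base = fit_addition(linearize(cya_solution_series))
        scaled_blends = [
            AdditionBlend(
                b.blend_id, b.m_x, b.m_y, b.m_z,
                _uq(b.r_obs.value * f, b.r_obs.u),
            )
            for b in cya_solution_series.blends
        ]
        scaled = fit_addition(
            linearize(AdditionSeries(scaled_blends, cya_solution_series.w_Z))
        )
        assert scaled.a0 == pytest.approx(base.a0 * f, rel=1e-12)
        assert scaled.a1 == pytest.approx(base.a1 * f, rel=1e-12)
        assert scaled.ratio == pytest.approx(base.ratio, rel=1e-12)

    def test_outlier_exclusion_reports_both_fits(self, cya_solution_series):
        fit_all, _ = quantify(cya_solution_series)
        fit_excl, _ = quantify(cya_solution_series, exclude=["3"])
        assert len(fit_excl.points) == 3
        assert fit_excl.ratio != pytest.approx(fit_all.ratio, rel=1e-6)


class TestMatchingReport:
    def test_mel_solution_statistics(self, mel_solution_series):
        """Mean and sd of the four observed ratios at printed precision."""
        rep = matching_report(mel_solution_series)
        assert round(rep.mean, 3) == 1.221
        assert round(rep.sd, 3) == 0.008
        assert rep.rsd == pytest.approx(0.006, abs=5e-4)

    def test_cya_solution_statistics(self, cya_solution_series):
        rep = matching_report(cya_solution_series)
        assert round(rep.mean, 3) == 1.056
        assert round(rep.sd, 3) == 0.008
        assert rep.rsd == pytest.approx(0.008, abs=5e-4)

    def test_constant_ratios_have_zero_sd(self):
        series = _series([(50, 50, 0, 1.1), (50, 100, 50, 1.1)])
        rep = matching_report(series)
        assert rep.sd == 0.0
        assert not rep.flagged

    def test_large_spread_is_flagged_not_blocking(self, pt_sample_series):
        rep = matching_report(pt_sample_series)
        assert rep.flagged  # unmatched PT series: RSD ~9%
        quantify(pt_sample_series)  # still computes
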