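"""Reference-model arithmetic: splines, M/S curves, Z-scores, LLN."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spirolms import (
    DEFAULT_Z_CRITICAL,
    LMSReferenceModel,
    ModelRegistry,
    SplineTable,
    critical_z,
    evaluate_piecewise,
    export_lookup_table,
    lln,
    predict_cohort,
    predict_cv,
    predict_mean,
    spline_at,
    z_score,
)
from spirolms.models import (
    DomainError,
    ModelValidationError,
    lookup_table_to_registry,
)

from conftest import make_smooth_piecewise


def simple_model(**kw) -> LMSReferenceModel:
    defaults = dict(
        outcome="fev1", sex="F",
        m_b0=0.0, m_b1=0.0, m_b2=0.0, s_b0=0.0, s_b1=0.0,
    )
    defaults.update(kw)
    return LMSReferenceModel(**defaults)


class TestSplineTable:
    def test_empty_table_is_constant_zero(self):
        assert spline_at(SplineTable(), 55.3) == 0.0

    def test_linear_rule_midpoint(self):
        t = SplineTable((20.0, 40.0), (0.1, 0.3), interpolation="linear")
        assert spline_at(t, 30.0) == pytest.approx(0.2, abs=1e-12)

    def test_single_knot_constant_everywhere(self):
        t = SplineTable((50.0,), (0.7,))
        assert spline_at(t, 20.0) == 0.7
        assert spline_at(t, 90.0) == 0.7

    def test_flat_extrapolation_with_warning(self, caplog):
        t = SplineTable((20.0, 90.0), (0.0, 0.5), interpolation="linear")
        with caplog.at_level("WARNING", logger="spirolms.models"):
            val = spline_at(t, 95.0)
        assert val == pytest.approx(0.5)
        assert any("flat extrapolation" in r.message for r in caplog.records)

    def test_pchip_interpolates_through_knots(self):
        t = SplineTable((20.0, 40.0, 60.0), (0.0, 0.2, -0.1))
        assert spline_at(t, 40.0) == pytest.approx(0.2, abs=1e-12)

    def test_nonincreasing_ages_rejected(self):
        with pytest.raises(ModelValidationError):
            SplineTable((40.0, 20.0), (0.0, 0.1))


class TestMeanAndScatter:
    def test_all_zero_coefficients_give_unity(self):
        m = simple_model()
        assert predict_mean(m, 47.0, 171.0) == pytest.approx(1.0)
        assert predict_cv(m, 47.0) == pytest.approx(1.0)

    def test_closed_form_height_exponent(self):
        m = simple_model(m_b0=np.log(2.0), m_b1=1.0)
        assert predict_mean(m, 50.0, np.e) == pytest.approx(2.0 * np.e, rel=1e-12)

    def test_mean_against_arithmetic_oracle(self):
        # exp(-10 + 2.2*ln(177) + 0.03*ln(45)), computed independently
        m = simple_model(m_b0=-10.0, m_b1=2.2, m_b2=0.03)
        assert predict_mean(m, 45.0, 177.0) == pytest.approx(
            4.489445899053152, rel=1e-10
        )

    def test_cv_constant_and_oracle(self):
        m = simple_model(s_b0=np.log(0.1))
        for age in (25.0, 50.0, 88.0):
            assert predict_cv(m, age) == pytest.approx(0.1, rel=1e-12)
        m2 = simple_model(s_b0=-3.0, s_b1=0.2)
        # exp(-3 + 0.2*ln(50)), computed independently
        assert predict_cv(m2, 50.0) == pytest.approx(0.10887058465248702, rel=1e-10)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_domain_errors(self, bad):
        m = simple_model()
        with pytest.raises(DomainError):
            predict_mean(m, bad, 170.0)
        with pytest.raises(DomainError):
            predict_mean(m, 50.0, bad)

    @given(
        h1=st.floats(140, 200), h2=st.floats(140, 200),
        age=st.floats(20, 90), b1=st.floats(0.5, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_mean_monotone_in_height(self, h1, h2, age, b1):
        m = simple_model(m_b0=-8.0, m_b1=b1, m_b2=-0.3)
        lo_h, hi_h = sorted((h1, h2))
        if hi_h - lo_h > 1e-9:
            assert predict_mean(m, age, hi_h) > predict_mean(m, age, lo_h)


class TestZScoreAndLLN:
    def setup_method(self):
        self.m = simple_model(m_b0=-8.0, m_b1=2.0, m_b2=-0.3, s_b0=np.log(0.12))

    def test_observed_at_mean_scores_zero(self):
        M = predict_mean(self.m, 50.0, 165.0)
        assert z_score(self.m, M, 50.0, 165.0) == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_above_mean_scores_one(self):
        M = predict_mean(self.m, 50.0, 165.0)
        S = predict_cv(self.m, 50.0)
        assert z_score(self.m, M * (1 + S), 50.0, 165.0) == pytest.approx(1.0)

    def test_lln_boundary_value(self):
        M = predict_mean(self.m, 50.0, 165.0)
        S = predict_cv(self.m, 50.0)
        z = z_score(self.m, M * (1 - 1.6449 * S), 50.0, 165.0)
        assert z == pytest.approx(-1.6449, abs=1e-10)

    def test_lln_closed_form_oracle(self):
        # M = 3.0 L and S = 0.12 give 3.0*(1 - 1.6449*0.12) = 2.407836 L
        m = simple_model(m_b0=np.log(3.0), s_b0=np.log(0.12))
        assert lln(m, 50.0, 165.0) == pytest.approx(2.407836, abs=1e-9)

    def test_zero_scatter_lln_equals_mean(self):
        m = simple_model(m_b0=np.log(3.0), s_b0=np.log(1e-12))
        assert lln(m, 40.0, 160.0) == pytest.approx(
            predict_mean(m, 40.0, 160.0), rel=1e-9
        )

    @given(age=st.floats(21, 89), height=st.floats(140, 200))
    @settings(max_examples=50, deadline=None)
    def test_lln_zscore_round_trip(self, age, height):
        v = lln(self.m, age, height)
        assert z_score(self.m, v, age, height) == pytest.approx(
            DEFAULT_Z_CRITICAL, abs=1e-12
        )

    @given(age=st.floats(21, 89), height=st.floats(140, 200))
    @settings(max_examples=50, deadline=None)
    def test_lln_below_mean_for_positive_scatter(self, age, height):
        assert lln(self.m, age, height) < predict_mean(self.m, age, height)

    def test_general_L_reduces_to_linear_at_one(self):
        m1 = simple_model(m_b0=1.0, s_b0=np.log(0.1), L=1.0)
        m2 = simple_model(m_b0=1.0, s_b0=np.log(0.1), L=0.5)
        M = predict_mean(m1, 50.0, 165.0)
        assert z_score(m1, 0.9 * M, 50.0, 165.0) == pytest.approx(-1.0)
        # Box-Cox form differs from linear away from L=1
        assert z_score(m2, 0.9 * M, 50.0, 165.0) != pytest.approx(-1.0)

    def test_critical_z_is_fifth_percentile(self):
        assert round(critical_z(0.05), 2) == -1.64


class TestPiecewise:
    def test_single_segment_horner_oracle(self):
        from spirolms import PolySegment, PiecewisePolyModel

        seg = PolySegment(
            age_interval=(20.0, 90.0),
            mean_terms=((0, 0, 0.5), (1, 0, 0.02), (2, 0, -3e-4), (3, 0, 1e-6), (0, 1, 0.01)),
        )
        m = PiecewisePolyModel(outcome="fev1", sex="M", segments=(seg,))
        # Horner evaluation of the same polynomial, computed independently
        assert evaluate_piecewise(m, 60.0, 170.0)["mean"] == pytest.approx(
            2.536, abs=1e-12
        )

    def test_smooth_join_continuity(self):
        m = make_smooth_piecewise()
        eps = 1e-7
        below = evaluate_piecewise(m, 50.0 - eps, 175.0)["mean"]
        above = evaluate_piecewise(m, 50.0 + eps, 175.0)["mean"]
        assert abs(above - below) < 1e-6
        left, right = m.segments
        assert abs(left.dmean_dage(50.0, 175.0) - right.dmean_dage(50.0, 175.0)) < 1e-9

    def test_non_smooth_join_rejected(self):
        from spirolms import PolySegment, PiecewisePolyModel

        left = PolySegment((20.0, 50.0), ((0, 0, 1.0), (1, 0, 0.01)))
        right = PolySegment((50.0, 90.0), ((0, 0, 1.0), (1, 0, 0.02)))
        with pytest.raises(ModelValidationError):
            PiecewisePolyModel(outcome="fev1", sex="M", segments=(left, right))

    def test_no_extrapolation_outside_range(self):
        m = make_smooth_piecewise()
        with pytest.raises(DomainError):
            evaluate_piecewise(m, 95.0, 170.0)

    def test_lln_uses_scatter_segments(self):
        m = make_smooth_piecewise()
        mean = evaluate_piecewise(m, 60.0, 175.0)["mean"]
        assert m.lln(60.0, 175.0) == pytest.approx(mean + DEFAULT_Z_CRITICAL * 0.4)


class TestCohortPrediction:
    def _cohort(self, registry, z0):
        rows = []
        for i, (sex, age, height) in enumerate(
            [("F", 35.0, 168.0), ("F", 62.0, 161.0), ("M", 48.0, 180.0)]
        ):
            mf = registry.get_model("fev1", sex)
            mv = registry.get_model("fvc", sex)
            fev1 = predict_mean(mf, age, height) * (1 + predict_cv(mf, age) * z0)
            fvc = predict_mean(mv, age, height) * (1 + predict_cv(mv, age) * z0)
            rows.append(
                dict(subject_id=f"s{i}", sex=sex, age=age, height=height,
                     weight=70.0, fev1=fev1, fvc=fvc, smoking="never")
            )
        return pd.DataFrame(rows)

    def test_observed_at_mean_gives_zero_z_and_no_flags(self, truth_registry):
        cohort = self._cohort(truth_registry, 0.0)
        pred = predict_cohort(truth_registry, cohort, "fev1")
        assert np.allclose(pred["z"], 0.0, atol=1e-10)
        assert not pred["below_lln"].any()

    @pytest.mark.parametrize("z0", [-2.0, -1.0, 1.5])
    def test_constructed_z_reproduced(self, truth_registry, z0):
        cohort = self._cohort(truth_registry, z0)
        for outcome in ("fev1", "fvc"):
            pred = predict_cohort(truth_registry, cohort, outcome)
            assert np.allclose(pred["z"], z0, atol=1e-9)
            assert pred["below_lln"].all() == (z0 < DEFAULT_Z_CRITICAL)

    def test_missing_height_skipped_and_logged(self, truth_registry, caplog):
        cohort = self._cohort(truth_registry, 0.0)
        cohort.loc[0, "height"] = np.nan
        with caplog.at_level("WARNING", logger="spirolms.models"):
            pred = predict_cohort(truth_registry, cohort, "fev1")
        assert len(pred) == 2
        assert any("skipping" in r.message for r in caplog.records)


class TestLookupTable:
    def test_export_matches_formula_and_round_trips(self, truth_registry):
        grid = np.arange(25.0, 86.0, 1.0)
        heights = {"F": 164.0, "M": 178.0}
        table = export_lookup_table(truth_registry, grid, heights)
        # M column equals predict_mean at each grid age
        sub = table[(table["outcome"] == "fev1") & (table["sex"] == "F")]
        model = truth_registry.get_model("fev1", "F")
        expected = predict_mean(model, sub["age"].to_numpy(), 164.0)
        assert np.allclose(sub["M"].to_numpy(), expected, rtol=1e-12)

        coefs = {
            key: dict(m_b0=m.m_b0, m_b1=m.m_b1, m_b2=m.m_b2, s_b0=m.s_b0, s_b1=m.s_b1)
            for key, m in truth_registry.items()
        }
        rebuilt = lookup_table_to_registry(table, coefs)
        probe_ages = np.array([30.0, 47.5, 72.0])
        for key in truth_registry:
            a = probe_ages
            orig = predict_mean(truth_registry[key], a, 170.0)
            new = predict_mean(rebuilt[key], a, 170.0)
            assert np.allclose(orig, new, atol=1e-4)

    def test_grid_outside_model_range_rejected(self, truth_registry):
        with pytest.raises(DomainError):
            export_lookup_table(truth_registry, [10.0, 50.0], {"F": 164.0, "M": 178.0})
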