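"""Model comparison: residual tests, below-LLN tables, height trend."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from spirolms import (
    GeneratorConfig,
    ModelRegistry,
    compare_models,
    generate_cohort,
    height_trend,
    residual_table,
    z_table,
)
from spirolms.compare import InsufficientDataError
from spirolms.models import DEFAULT_Z_CRITICAL


def scaled_registry(registry: ModelRegistry, factor: float, name: str) -> ModelRegistry:
    """Registry with every predicted mean multiplied by ``factor``."""
    out = ModelRegistry(name=name)
    for model in registry.values():
        out.add(
            replace(model, m_b0=model.m_b0 + np.log(factor), model_id=f"{name}_{model.outcome}_{model.sex}")
        )
    return out


@pytest.fixture(scope="module")
def cohort(truth_registry):
    return generate_cohort(GeneratorConfig(seed=33, pathology_fraction=0.0))


class TestResidualTable:
    def test_identical_models_report_no_difference(self, cohort, truth_registry):
        twin = scaled_registry(truth_registry, 1.0, "twin")
        rep = residual_table(cohort, [truth_registry, twin])
        assert (rep.pairwise["paired_t_p"] == 1.0).all()
        assert (rep.anova["anova_p"] == 1.0).all()
        r = rep.residuals
        for outcome in ("fev1", "fvc", "ratio"):
            sub = r[r["outcome"] == outcome]
            assert sub["resid_mean"].nunique() == 1

    def test_scaled_down_comparator_detected(self, cohort, truth_registry):
        low = scaled_registry(truth_registry, 0.95, "low")
        rep = residual_table(cohort, [truth_registry, low])
        r = rep.residuals
        fe = r[r["outcome"] == "fev1"].set_index("model")
        # the low-predicting model leaves positive residuals ...
        assert fe.loc["low", "resid_mean"] > fe.loc["truth", "resid_mean"]
        diff = fe.loc["low", "resid_mean"] - fe.loc["truth", "resid_mean"]
        # ... by exactly 5% of the reference model's mean prediction
        mean_pred = cohort["fev1"].mean() - fe.loc["truth", "resid_mean"]
        assert diff == pytest.approx(0.05 * mean_pred, rel=1e-9)
        # paired comparison and ANOVA are decisive at n ~ 284
        pw = rep.pairwise[rep.pairwise["outcome"] == "fev1"].iloc[0]
        assert pw["paired_t_p"] < 1e-6
        assert rep.anova.set_index("outcome").loc["fev1", "anova_p"] < 1e-6

    def test_residual_sign_convention(self, cohort, truth_registry):
        rep = residual_table(cohort, [truth_registry, scaled_registry(truth_registry, 0.9, "lo")])
        r = rep.residuals.set_index(["outcome", "model"])
        # residual = observed - predicted: scaling predictions down by 10%
        # shifts the mean residual up
        assert r.loc[("fvc", "lo"), "resid_mean"] > r.loc[("fvc", "truth"), "resid_mean"]

    def test_needs_two_registries_and_three_subjects(self, cohort, truth_registry):
        with pytest.raises(ValueError):
            residual_table(cohort, [truth_registry])
        with pytest.raises(InsufficientDataError):
            residual_table(cohort.head(2), [truth_registry, truth_registry])


class TestZTable:
    def test_zero_z_cohort_has_no_flags(self, truth_registry):
        from test_screening import build_cohort_at_z

        cohort = build_cohort_at_z(truth_registry, np.zeros(30))
        rep = z_table(cohort, [truth_registry, scaled_registry(truth_registry, 1.0, "t2")],
                      outcomes=("ratio",))
        assert (rep.below_lln["pct_below_lln"] == 0.0).all()

    def test_below_lln_monotone_in_scale_factor(self, cohort, truth_registry):
        """Lower predicted means flag fewer subjects below the LLN."""
        regs = [scaled_registry(truth_registry, f, f"s{i}")
                for i, f in enumerate((0.90, 0.95, 1.00, 1.05))]
        rep = z_table(cohort, regs, outcomes=("fev1",))
        tab = rep.below_lln.groupby("model")["n_below"].sum()
        counts = [tab[f"s{i}"] for i in range(4)]
        assert counts == sorted(counts)

    def test_healthy_cohort_near_five_percent(self, truth_registry):
        big = generate_cohort(GeneratorConfig(seed=77, n_per_sex=20000,
                                              pathology_fraction=0.0))
        rep = z_table(big, [truth_registry, scaled_registry(truth_registry, 1.0, "t2")],
                      outcomes=("fev1",))
        sub = rep.below_lln[rep.below_lln["model"] == "truth"]
        pct = (sub["n_below"].sum() / sub["n"].sum()) * 100
        assert pct == pytest.approx(5.0, abs=0.5)

    def test_density_grid_integrates_to_one(self, cohort, truth_registry):
        rep = z_table(cohort, [truth_registry, scaled_registry(truth_registry, 0.95, "lo")],
                      outcomes=("fev1",))
        for _, grp in rep.z_density.groupby("model"):
            area = np.trapezoid(grp["density"], grp["z"])
            assert area == pytest.approx(1.0, abs=0.05)


class TestHeightTrend:
    def test_exact_line_recovered(self):
        ages = np.linspace(20, 90, 60)
        cohort = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(60)],
                "sex": "F",
                "age": ages,
                "height": 180.0 - 0.2 * (ages - 20.0),
                "weight": 60.0,
                "fev1": 3.0,
                "fvc": 4.0,
                "smoking": "never",
            }
        )
        res = height_trend(cohort, "F")
        assert res["slope_magnitude"] == pytest.approx(0.2, abs=1e-10)
        assert res["direction"] == "decrease"
        assert res["r2"] == pytest.approx(1.0, abs=1e-10)

    def test_constant_height_gives_zero_slope(self):
        cohort = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "sex": "M",
                "age": [25.0, 50.0, 75.0],
                "height": [178.0, 178.0, 178.0],
                "weight": 80.0,
                "fev1": 4.0,
                "fvc": 5.0,
                "smoking": "never",
            }
        )
        res = height_trend(cohort, "M")
        assert res["slope_magnitude"] == 0.0
        assert res["F"] == 0.0

    def test_default_female_generator_slope(self):
        cohort = generate_cohort(GeneratorConfig(seed=55, n_per_sex=5000,
                                                 pathology_fraction=0.0))
        res = height_trend(cohort, "F")
        assert res["slope_magnitude"] == pytest.approx(0.19, abs=0.015)
        assert res["p"] < 1e-10


class TestFullReport:
    def test_compare_models_assembles_all_tables(self, cohort, truth_registry):
        rep = compare_models(cohort, [truth_registry,
                                      scaled_registry(truth_registry, 0.95, "lo")])
        assert not rep.residuals.empty
        assert not rep.anova.empty
        assert not rep.below_lln.empty
        assert not rep.z_summary.empty
        assert set(rep.height_trend["sex"]) == {"F", "M"}
        d = rep.to_dict()
        assert {"residuals", "anova", "pairwise", "below_lln",
                "z_summary", "height_trend"} <= set(d)
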