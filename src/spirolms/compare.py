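"""Comparison of competing reference models on a common cohort.

Implements the comparison protocol used to contrast locally rederived LMS
equations with published reference sets:

* per-model residual statistics (observed - predicted), with a one-sample
  t-test of zero mean and a Kolmogorov–Smirnov normality test;
* one-way repeated-measures ANOVA of residuals across models with post-hoc
  paired t-tests and two-sample KS tests between model pairs;
* Z-score summaries and the percentage of subjects below each model's LLN,
  by sex;
* kernel-density summaries of the Z-score distributions (tabulated grids,
  for external plotting);
* the cross-sectional height-versus-age regression.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import DEFAULT_Z_CRITICAL, ModelRegistry, predict_cohort

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few subjects for the requested statistical comparison."""


@dataclass
class ComparisonReport:
    """Container for the cross-model comparison tables.

    Attributes
    ----------
    residuals : DataFrame
        ``outcome, model, n, resid_mean, resid_sd, t_p, ks_p``.
    anova : DataFrame
        ``outcome, anova_p`` (repeated-measures across models).
    pairwise : DataFrame
        ``outcome, model_a, model_b, paired_t_p, ks_2samp_p``.
    below_lln : DataFrame
        ``outcome, model, sex, n, n_below, pct_below_lln``.
    z_summary : DataFrame
        ``outcome, model, z_mean, z_sd, z_p05, z_p50, z_p95``.
    z_density : DataFrame
        ``outcome, model, z, density`` — Gaussian-kernel density grids.
    height_trend : DataFrame
        per-sex OLS of height on age.
    """

    residuals: pd.DataFrame = field(default_factory=pd.DataFrame)
    anova: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    below_lln: pd.DataFrame = field(default_factory=pd.DataFrame)
    z_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    z_density: pd.DataFrame = field(default_factory=pd.DataFrame)
    height_trend: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            name: getattr(self, name).to_dict(orient="records")
            for name in (
                "residuals",
                "anova",
                "pairwise",
                "below_lln",
                "z_summary",
                "height_trend",
            )
        }


def _predictions(
    cohort: pd.DataFrame,
    registries: list[ModelRegistry],
    outcome: str,
    z_critical: float,
) -> dict[str, pd.DataFrame]:
    out = {}
    for reg in registries:
        pred = predict_cohort(reg, cohort, outcome, z_critical)
        out[reg.name] = pred.set_index("subject_id").loc[cohort["subject_id"]]
    return out


def residual_table(
    cohort: pd.DataFrame,
    registries: list[ModelRegistry],
    outcomes: tuple[str, ...] = ("fev1", "fvc", "ratio"),
    z_critical: float = DEFAULT_Z_CRITICAL,
) -> ComparisonReport:
    """Residual statistics and tests across models (partial report).

    For each outcome: per-model mean and SD of the residuals, a one-sample
    t-test of zero mean, a KS normality test; across models a one-way
    repeated-measures ANOVA on the within-subject residuals with post-hoc
    paired t-tests, plus two-sample KS tests between model pairs.
    Degenerate comparisons between identical models report p = 1
    ("no difference") instead of NaN.
    """
    if len(registries) < 2:
        raise ValueError("need at least two model registries to compare")
    if len(cohort) < 3:
        raise InsufficientDataError("need at least 3 subjects")

    resid_rows, anova_rows, pair_rows = [], [], []
    for outcome in outcomes:
        preds = _predictions(cohort, registries, outcome, z_critical)
        resids = {name: p["residual"].to_numpy(float) for name, p in preds.items()}
        for name, r in resids.items():
            sd = float(np.std(r, ddof=1))
            if sd > 0:
                t_p = float(stats.ttest_1samp(r, 0.0).pvalue)
                ks_p = float(stats.kstest(r, "norm", args=(r.mean(), sd)).pvalue)
            else:
                t_p = 1.0 if abs(r.mean()) < 1e-12 else 0.0
                ks_p = 1.0
            resid_rows.append(
                {
                    "outcome": outcome,
                    "model": name,
                    "n": len(r),
                    "resid_mean": float(r.mean()),
                    "resid_sd": sd,
                    "t_p": t_p,
                    "ks_p": ks_p,
                }
            )
        anova_rows.append(
            {"outcome": outcome, "anova_p": _repeated_anova(list(resids.values()))}
        )
        for a, b in itertools.combinations(resids, 2):
            diff = resids[a] - resids[b]
            if np.allclose(diff, diff[0]) and abs(diff[0]) < 1e-12:
                t_p = 1.0  # identical predictions: no difference by construction
            else:
                t_p = float(stats.ttest_rel(resids[a], resids[b]).pvalue)
                if np.isnan(t_p):
                    t_p = 1.0
            ks2 = float(stats.ks_2samp(resids[a], resids[b]).pvalue)
            pair_rows.append(
                {
                    "outcome": outcome,
                    "model_a": a,
                    "model_b": b,
                    "paired_t_p": t_p,
                    "ks_2samp_p": ks2,
                }
            )
    return ComparisonReport(
        residuals=pd.DataFrame(resid_rows),
        anova=pd.DataFrame(anova_rows),
        pairwise=pd.DataFrame(pair_rows),
    )


def _repeated_anova(groups: list[np.ndarray]) -> float:
    """One-way repeated-measures ANOVA p-value across paired columns.

    Computed directly from the two-way (subject x model) decomposition.
    Returns 1.0 for degenerate zero-variance designs.
    """
    Y = np.column_stack(groups)
    n, k = Y.shape
    grand = Y.mean()
    ss_models = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((Y.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_err = ss_tot - ss_models - ss_subj
    df_models = k - 1
    df_err = (n - 1) * (k - 1)
    if df_err <= 0 or ss_err <= 1e-300:
        return 1.0 if ss_models < 1e-12 else 0.0
    F = (ss_models / df_models) / (ss_err / df_err)
    return float(stats.f.sf(F, df_models, df_err))


def z_table(
    cohort: pd.DataFrame,
    registries: list[ModelRegistry],
    outcomes: tuple[str, ...] = ("fev1", "fvc", "ratio"),
    z_critical: float = DEFAULT_Z_CRITICAL,
    density_grid: np.ndarray | None = None,
) -> ComparisonReport:
    """Z-score distributions and below-LLN percentages (partial report).

    Percentages are ``100 * count(z < z_critical) / n`` per sex, model and
    outcome; Z-score distributions are additionally summarized as Gaussian
    kernel densities (Silverman bandwidth) on a common grid.
    """
    if density_grid is None:
        density_grid = np.linspace(-4.0, 4.0, 161)
    lln_rows, summary_rows, dens_rows = [], [], []
    for outcome in outcomes:
        preds = _predictions(cohort, registries, outcome, z_critical)
        for name, p in preds.items():
            z = p["z"].to_numpy(float)
            summary_rows.append(
                {
                    "outcome": outcome,
                    "model": name,
                    "z_mean": float(z.mean()),
                    "z_sd": float(np.std(z, ddof=1)),
                    "z_p05": float(np.percentile(z, 5)),
                    "z_p50": float(np.percentile(z, 50)),
                    "z_p95": float(np.percentile(z, 95)),
                }
            )
            if np.std(z) > 0:
                kde = stats.gaussian_kde(z, bw_method="silverman")
                dens = kde(density_grid)
            else:
                dens = np.zeros_like(density_grid)
            dens_rows.append(
                pd.DataFrame(
                    {
                        "outcome": outcome,
                        "model": name,
                        "z": density_grid,
                        "density": dens,
                    }
                )
            )
            for sex, grp in p.groupby("sex"):
                zs = grp["z"].to_numpy(float)
                n_below = int((zs < z_critical).sum())
                lln_rows.append(
                    {
                        "outcome": outcome,
                        "model": name,
                        "sex": sex,
                        "n": len(zs),
                        "n_below": n_below,
                        "pct_below_lln": 100.0 * n_below / len(zs),
                    }
                )
    return ComparisonReport(
        below_lln=pd.DataFrame(lln_rows),
        z_summary=pd.DataFrame(summary_rows),
        z_density=pd.concat(dens_rows, ignore_index=True),
    )


def height_trend(cohort: pd.DataFrame, sex: str) -> dict:
    """Ordinary least squares of height (cm) on age (years) for one sex.

    Returns the annual *decline* as a positive magnitude with a direction
    flag, together with the 95% CI of the magnitude, r², F and p.
    """
    import statsmodels.api as sm

    sub = cohort.loc[cohort["sex"] == sex]
    if len(sub) < 3:
        raise InsufficientDataError(f"need >= 3 subjects of sex {sex!r}")
    age = sub["age"].to_numpy(float)
    if np.ptp(age) == 0:
        raise InsufficientDataError("zero age variance")
    if np.ptp(sub["height"].to_numpy(float)) == 0:
        # degenerate flat cohort: no trend by construction
        return {
            "sex": sex,
            "slope_magnitude": 0.0,
            "direction": "decrease",
            "ci_low": 0.0,
            "ci_high": 0.0,
            "r2": 0.0,
            "F": 0.0,
            "p": 1.0,
        }
    X = sm.add_constant(age)
    fit = sm.OLS(sub["height"].to_numpy(float), X).fit()
    slope = float(fit.params[1])
    ci = fit.conf_int(alpha=0.05)[1]
    declining = slope <= 0
    mag_ci = sorted(abs(float(c)) for c in ci) if declining else [float(c) for c in ci]
    return {
        "sex": sex,
        "slope_magnitude": abs(slope),
        "direction": "decrease" if declining else "increase",
        "ci_low": mag_ci[0],
        "ci_high": mag_ci[1],
        "r2": float(fit.rsquared),
        "F": float(fit.fvalue),
        "p": float(fit.f_pvalue),
    }


def compare_models(
    cohort: pd.DataFrame,
    registries: list[ModelRegistry],
    outcomes: tuple[str, ...] = ("fev1", "fvc", "ratio"),
    z_critical: float = DEFAULT_Z_CRITICAL,
) -> ComparisonReport:
    """Full comparison report: residual tables, Z tables and height trends."""
    rep = residual_table(cohort, registries, outcomes, z_critical)
    ztab = z_table(cohort, registries, outcomes, z_critical)
    rep.below_lln = ztab.below_lln
    rep.z_summary = ztab.z_summary
    rep.z_density = ztab.z_density
    trends = []
    for sex in ("F", "M"):
        if (cohort["sex"] == sex).sum() >= 3:
            trends.append(height_trend(cohort, sex))
    rep.height_trend = pd.DataFrame(trends)
    return rep
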