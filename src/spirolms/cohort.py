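"""Synthetic spirometry cohorts with a known ground truth.

Generates adult cohorts whose statistical structure mirrors a
population-based Northern-European study sample: ages uniform on 20–90
years, a cross-sectional decline of standing height with age (0.19 cm/year
in females, 0.14 cm/year in males), and FEV1/FVC volumes drawn around
sex-specific LMS truth curves.  A configurable fraction of subjects carries
an obstructive "pathology" (multiplicatively reduced FEV1, optionally also
reduced FVC) so that downstream LLN screening has something to find.

Outcome noise model
-------------------
Given the truth median ``M(age, height)`` and coefficient of variation
``S(age)``, outcomes are drawn as ``y = M * (1 + S * z)`` with ``z``
standard normal (FEV1 and FVC share a correlated ``z`` pair), i.e. normal
residuals around the predicted mean with SD ``M*S``.  This matches the
``L = 1`` assumption of the reference models exactly: the linear Z-score of
a healthy subject under the generating model is standard normal by
construction, so 5% of a healthy cohort falls below the LLN.  Draws are
rejected and redrawn where they would violate ``0 < fev1 <= fvc``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    LMSReferenceModel,
    ModelRegistry,
    predict_cv,
    predict_mean,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A generator configuration field is invalid."""


# ---------------------------------------------------------------------------
# Ground-truth reference models
# ---------------------------------------------------------------------------

# Log-linear truth coefficients (no spline terms), tuned once so the
# generated sex x age-band means approximate a heart-healthy adult cohort
# from Northern Sweden; committed as frozen constants.  The ratio model is
# the exact quotient of the FEV1 and FVC models (coefficient differences).
_TRUTH_M: dict[tuple[str, str], tuple[float, float, float]] = {
    # (outcome, sex): (m_b0, m_b1, m_b2)
    ("fvc", "F"): (-8.313301, 2.10, -0.297473),
    ("fev1", "F"): (-7.370636, 1.95, -0.402365),
    ("fvc", "M"): (-8.454273, 2.10, -0.212535),
    ("fev1", "M"): (-7.467829, 1.95, -0.335585),
}
_TRUTH_S: dict[str, tuple[float, float]] = {
    # outcome: (s_b0, s_b1); S(age) = exp(s_b0 + s_b1*log(age))
    # ratio S is the CV implied by the correlated FEV1/FVC draws,
    # sqrt(S1^2 + S2^2 - 2*rho*S1*S2), so the truth registry describes the
    # distribution the generator actually produces.
    "fev1": (-3.598, 0.409),
    "fvc": (-3.7735, 0.4015),
    "ratio": (-4.2248, 0.4135),
}

#: Correlation of the FEV1 and FVC noise draws; chosen so the implied CV of
#: the FEV1/FVC ratio matches the ratio truth S at mid-age.
DEFAULT_FEV1_FVC_CORRELATION: float = 0.84


def default_truth_registry() -> ModelRegistry:
    """Registry of the six frozen ground-truth LMS models (3 outcomes x 2 sexes)."""
    reg = ModelRegistry(name="truth")
    for sex in ("F", "M"):
        for outcome in ("fev1", "fvc"):
            b0, b1, b2 = _TRUTH_M[(outcome, sex)]
            s0, s1 = _TRUTH_S[outcome]
            reg.add(
                LMSReferenceModel(
                    outcome=outcome,
                    sex=sex,
                    m_b0=b0,
                    m_b1=b1,
                    m_b2=b2,
                    s_b0=s0,
                    s_b1=s1,
                    model_id=f"truth_{outcome}_{sex}",
                )
            )
        fe, fv = _TRUTH_M[("fev1", sex)], _TRUTH_M[("fvc", sex)]
        s0, s1 = _TRUTH_S["ratio"]
        reg.add(
            LMSReferenceModel(
                outcome="ratio",
                sex=sex,
                m_b0=fe[0] - fv[0],
                m_b1=fe[1] - fv[1],
                m_b2=fe[2] - fv[2],
                s_b0=s0,
                s_b1=s1,
                model_id=f"truth_ratio_{sex}",
            )
        )
    return reg


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeightTrend:
    """Cross-sectional height-vs-age model: intercept at age 20 plus a
    (non-positive) slope in cm/year, with normal scatter."""

    intercept_at_age20: float
    slope: float
    sd: float

    def __post_init__(self) -> None:
        if self.slope > 0:
            raise ConfigurationError("height_trend.slope must be <= 0 (cm/year)")
        if self.sd < 0:
            raise ConfigurationError("height_trend.sd must be >= 0")

    def mean_at(self, age) -> np.ndarray:
        return self.intercept_at_age20 + self.slope * (np.asarray(age, float) - 20.0)


#: Default height trends: the 40-60-year band mean matches the cohort
#: tables exactly; slopes are the reported cross-sectional declines.
DEFAULT_HEIGHT_TRENDS: dict[str, HeightTrend] = {
    "F": HeightTrend(intercept_at_age20=171.5, slope=-0.19, sd=5.9),
    "M": HeightTrend(intercept_at_age20=184.0, slope=-0.14, sd=6.3),
}

#: Body weight (kg): sex-specific normal, clipped to a physiologic range.
DEFAULT_WEIGHT: dict[str, tuple[float, float]] = {"F": (64.8, 9.5), "M": (80.2, 12.9)}

#: Smoking-status frequencies; "unknown" mirrors a questionnaire added
#: mid-study and therefore missing for roughly half the cohort.
SMOKING_LEVELS: tuple[str, ...] = ("never", "current", "former", "unknown")
DEFAULT_SMOKING_P: tuple[float, ...] = (0.438, 0.049, 0.025, 0.488)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the study conditions: 142 subjects per sex
    (~284 total, ~269 after LLN screening), ages uniform on 20–90 years,
    a 6% pathology fraction with FEV1 reduced to 75% of its healthy draw
    (and, for 1/8 of the pathological subjects, FVC reduced to 80%).
    """

    n_per_sex: int = 142
    age_range: tuple[float, float] = (20.0, 90.0)
    height_trends: dict[str, HeightTrend] = field(
        default_factory=lambda: dict(DEFAULT_HEIGHT_TRENDS)
    )
    truth: ModelRegistry = field(default_factory=default_truth_registry)
    pathology_fraction: float = 0.06
    pathology_effect: float = 0.75
    pathology_fvc_fraction: float = 0.125
    pathology_fvc_effect: float = 0.80
    fev1_fvc_correlation: float = DEFAULT_FEV1_FVC_CORRELATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_sex < 1:
            raise ConfigurationError("n_per_sex must be >= 1")
        lo, hi = self.age_range
        if not (18.0 <= lo < hi <= 95.0):
            raise ConfigurationError("age_range must satisfy 18 <= lo < hi <= 95")
        if not 0.0 <= self.pathology_fraction < 1.0:
            raise ConfigurationError("pathology_fraction must be in [0, 1)")
        if not 0.0 < self.pathology_effect <= 1.0:
            raise ConfigurationError("pathology_effect must be in (0, 1]")
        if not 0.0 <= self.pathology_fvc_fraction <= 1.0:
            raise ConfigurationError("pathology_fvc_fraction must be in [0, 1]")
        if not 0.0 < self.pathology_fvc_effect <= 1.0:
            raise ConfigurationError("pathology_fvc_effect must be in (0, 1]")
        if not -1.0 < self.fev1_fvc_correlation < 1.0:
            raise ConfigurationError("fev1_fvc_correlation must be in (-1, 1)")
        for sex in ("F", "M"):
            if sex not in self.height_trends:
                raise ConfigurationError(f"height_trends missing sex {sex!r}")
            for outcome in ("fev1", "fvc"):
                if (outcome, sex) not in self.truth:
                    raise ConfigurationError(
                        f"truth registry missing model ({outcome!r}, {sex!r})"
                    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "height",
    "weight",
    "fev1",
    "fvc",
    "smoking",
]


def _draw_outcomes(
    rng: np.random.Generator,
    fev1_model: LMSReferenceModel,
    fvc_model: LMSReferenceModel,
    age: np.ndarray,
    height: np.ndarray,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated normal draws of (fev1, fvc), rejecting 0 < fev1 <= fvc
    violations by redrawing the offending rows."""
    n = len(age)
    m1 = np.asarray(predict_mean(fev1_model, age, height))
    s1 = np.asarray(predict_cv(fev1_model, age))
    m2 = np.asarray(predict_mean(fvc_model, age, height))
    s2 = np.asarray(predict_cv(fvc_model, age))
    fev1 = np.empty(n)
    fvc = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        k = len(todo)
        z_shared = rng.standard_normal(k)
        z_extra = rng.standard_normal(k)
        z_fvc = z_shared
        z_fev1 = rho * z_shared + np.sqrt(1.0 - rho**2) * z_extra
        cand_fvc = m2[todo] * (1.0 + s2[todo] * z_fvc)
        cand_fev1 = m1[todo] * (1.0 + s1[todo] * z_fev1)
        ok = (cand_fev1 > 0) & (cand_fvc > 0) & (cand_fev1 <= cand_fvc)
        fev1[todo[ok]] = cand_fev1[ok]
        fvc[todo[ok]] = cand_fvc[ok]
        todo = todo[~ok]
        if len(todo) == 0:
            break
    else:  # pragma: no cover - pathologically misconfigured truth models
        raise RuntimeError("could not satisfy 0 < fev1 <= fvc after 1000 rounds")
    return fev1, fvc


def generate_cohort(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort as a DataFrame (one row per subject).

    Columns: ``subject_id, sex, age, height, weight, fev1, fvc, smoking``.
    Ages are uniform on ``config.age_range``; heights follow the sex trend
    with normal scatter; FEV1/FVC are correlated normal draws around the
    truth curves (see module docstring); a ``pathology_fraction`` subset has
    FEV1 (and for a sub-fraction also FVC) multiplicatively reduced.
    Identical configurations (including seed) give identical output.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    frames = []
    for sex in ("F", "M"):
        n = config.n_per_sex
        trend = config.height_trends[sex]
        age = rng.uniform(lo, hi, n)
        height = trend.mean_at(age) + rng.standard_normal(n) * trend.sd
        height = np.clip(height, 130.0, 220.0)
        wmean, wsd = DEFAULT_WEIGHT[sex]
        weight = np.clip(wmean + rng.standard_normal(n) * wsd, 35.0, 160.0)
        fev1, fvc = _draw_outcomes(
            rng,
            config.truth.get_model("fev1", sex),
            config.truth.get_model("fvc", sex),
            age,
            height,
            config.fev1_fvc_correlation,
        )
        # obstructive pathology: reduced FEV1; a sub-fraction also small FVC
        n_path = int(round(config.pathology_fraction * n))
        if n_path:
            idx = rng.choice(n, size=n_path, replace=False)
            fev1[idx] *= config.pathology_effect
            n_small = int(round(config.pathology_fvc_fraction * n_path))
            if n_small:
                small = rng.choice(idx, size=n_small, replace=False)
                fvc[small] *= config.pathology_fvc_effect
                fev1[small] = np.minimum(fev1[small], fvc[small])
        smoking = rng.choice(
            SMOKING_LEVELS, size=n, p=np.asarray(DEFAULT_SMOKING_P) / sum(DEFAULT_SMOKING_P)
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{sex}{i + 1:05d}" for i in range(n)],
                    "sex": sex,
                    "age": age,
                    "height": height,
                    "weight": weight,
                    "fev1": fev1,
                    "fvc": fvc,
                    "smoking": smoking,
                }
            )
        )
    cohort = pd.concat(frames, ignore_index=True)
    return cohort[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# Age-band summaries
# ---------------------------------------------------------------------------

#: The study's age banding: under 40, 40-60 inclusive, over 60.
DEFAULT_AGE_BANDS: tuple[tuple[float, float], ...] = (
    (20.0, 40.0),
    (40.0, 60.0),
    (60.0, 90.0),
)

_SUMMARY_VARS = ("weight", "height", "bmi", "fvc", "fev1", "ratio")


def summarize_by_ageband(
    cohort: pd.DataFrame,
    bands: Sequence[tuple[float, float]] = DEFAULT_AGE_BANDS,
) -> pd.DataFrame:
    """Mean (SD) and range of each variable per sex x age band.

    Bands are half-open ``[lo, hi)`` except the last, which is closed, so
    consecutive bands partition the age axis with no subject in two bands.
    BMI is computed as ``weight / (height in m)**2`` and ``ratio`` is
    ``fev1/fvc``.  Empty cells yield rows of NaN with ``n = 0`` and a
    logged warning.
    """
    bands = [tuple(map(float, b)) for b in bands]
    for (a0, a1), (b0, b1) in zip(bands, bands[1:]):
        if b0 < a1:
            raise ValueError("age bands must be non-overlapping and ordered")
    df = cohort.copy()
    df["bmi"] = df["weight"] / (df["height"] / 100.0) ** 2
    df["ratio"] = df["fev1"] / df["fvc"]
    rows = []
    for sex in ("F", "M"):
        for i, (a0, a1) in enumerate(bands):
            last = i == len(bands) - 1
            in_band = (df["sex"] == sex) & (df["age"] >= a0)
            in_band &= (df["age"] <= a1) if last else (df["age"] < a1)
            sub = df.loc[in_band]
            n = len(sub)
            if n == 0:
                logger.warning("empty age band [%g, %g] for sex %s", a0, a1, sex)
            for var in _SUMMARY_VARS:
                vals = sub[var].to_numpy(float)
                rows.append(
                    {
                        "sex": sex,
                        "band_lo": a0,
                        "band_hi": a1,
                        "variable": var,
                        "n": n,
                        "mean": float(np.mean(vals)) if n else np.nan,
                        # SD reported as 0 for a single subject (flagged via n)
                        "sd": float(np.std(vals, ddof=1)) if n > 1 else (0.0 if n else np.nan),
                        "min": float(np.min(vals)) if n else np.nan,
                        "max": float(np.max(vals)) if n else np.nan,
                    }
                )
    return pd.DataFrame(rows)
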