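"""Reference models for spirometry outcomes.

Two model families are supported:

* :class:`LMSReferenceModel` — the LMS (lambda-mu-sigma) family used by the
  Global Lung Function Initiative: the predicted median ``M`` is an
  exponential of a linear predictor in ``log(height)`` and ``log(age)`` plus
  an age-indexed spline correction, and the coefficient of variation ``S``
  is an exponential of a linear predictor in ``log(age)`` plus its own
  spline.  The skewness index ``L`` is 1 by default (normal residuals).

* :class:`PiecewisePolyModel` — reference equations built from polynomial
  segments over abutting age ranges, merged so that the predicted curve and
  its first derivative are continuous at the joins (OLIN-style equations).

Both produce, per subject, a predicted mean, a predicted standard deviation,
a lower limit of normal (LLN, the 5th percentile of the healthy reference
distribution by default) and a Z-score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

logger = logging.getLogger(__name__)

Outcome = Literal["fev1", "fvc", "ratio"]
Sex = Literal["F", "M"]

OUTCOMES: tuple[str, ...] = ("fev1", "fvc", "ratio")
SEXES: tuple[str, ...] = ("F", "M")

#: Default critical Z for the lower limit of normal: Phi^-1(0.05),
#: rounded to four decimals (reported to two decimals as -1.64).
DEFAULT_Z_CRITICAL: float = -1.6449


def critical_z(percentile: float = 0.05) -> float:
    """Critical Z-score for a one-sided lower percentile.

    ``critical_z(0.05)`` is the Z-score that defines the lower limit of
    normal (5th percentile of a standard normal), approximately -1.64.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"percentile must be in (0, 1), got {percentile}")
    return float(stats.norm.ppf(percentile))


class ModelValidationError(ValueError):
    """A model object violates its structural invariants."""


class DomainError(ValueError):
    """An input lies outside the physical/model domain."""


# ---------------------------------------------------------------------------
# Spline lookup tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplineTable:
    """Age-indexed lookup table for the additive spline term of an LMS model.

    Parameters
    ----------
    ages
        Strictly increasing knot ages (years).  May be empty, in which case
        the table is the constant-zero spline.
    values
        Spline values at the knot ages (dimensionless, log-scale additive).
    interpolation
        ``"pchip"`` (monotone cubic, default) or ``"linear"``.

    Outside the knot range the table extrapolates flat (constant at the
    nearest knot value) and logs a warning, matching the convention of
    published LMS lookup tables which are only defined on their age grid.
    """

    ages: tuple[float, ...] = ()
    values: tuple[float, ...] = ()
    interpolation: str = "pchip"

    def __post_init__(self) -> None:
        ages = tuple(float(a) for a in self.ages)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if len(ages) != len(values):
            raise ModelValidationError("ages and values must have equal length")
        if len(ages) >= 2 and not np.all(np.diff(ages) > 0):
            raise ModelValidationError("spline knot ages must be strictly increasing")
        if self.interpolation not in ("pchip", "linear"):
            raise ModelValidationError(
                f"unknown interpolation rule {self.interpolation!r}"
            )

    @property
    def is_zero(self) -> bool:
        return len(self.ages) == 0

    def __call__(self, age):
        return spline_at(self, age)


ZERO_SPLINE = SplineTable()


def spline_at(table: SplineTable, age) -> np.ndarray | float:
    """Evaluate a spline lookup table at one or more ages.

    Empty tables evaluate to 0.  Single-knot tables are constant.  Ages
    outside the knot range are clamped to the nearest knot (flat
    extrapolation) with a logged warning.
    """
    age_arr = np.asarray(age, dtype=float)
    scalar = age_arr.ndim == 0
    age_arr = np.atleast_1d(age_arr)

    if table.is_zero:
        out = np.zeros_like(age_arr)
        return float(out[0]) if scalar else out
    knots = np.asarray(table.ages)
    vals = np.asarray(table.values)
    if len(knots) == 1:
        out = np.full_like(age_arr, vals[0])
        return float(out[0]) if scalar else out

    lo, hi = knots[0], knots[-1]
    tol = 1e-9 * max(1.0, abs(hi))
    outside = (age_arr < lo - tol) | (age_arr > hi + tol)
    if np.any(outside):
        logger.warning(
            "spline evaluated outside knot range [%g, %g] at %d age(s); "
            "using flat extrapolation",
            lo,
            hi,
            int(outside.sum()),
        )
    clamped = np.clip(age_arr, lo, hi)
    if table.interpolation == "linear":
        out = np.interp(clamped, knots, vals)
    else:
        out = PchipInterpolator(knots, vals)(clamped)
    out = np.asarray(out, dtype=float)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# LMS reference model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LMSReferenceModel:
    """LMS reference equations for one spirometry outcome and sex.

    Predicted median::

        M(age, height) = exp(m_b0 + m_b1*log(height) + m_b2*log(age) + Mspline(age))

    Coefficient of variation::

        S(age) = exp(s_b0 + s_b1*log(age) + Sspline(age))

    with height in cm, age in years and natural logarithms.  ``L`` is the
    skewness (Box–Cox power) index; ``L = 1`` corresponds to untransformed,
    normally distributed residuals and is the default.
    """

    outcome: str
    sex: str
    m_b0: float
    m_b1: float
    m_b2: float
    s_b0: float
    s_b1: float
    m_spline: SplineTable = ZERO_SPLINE
    s_spline: SplineTable = ZERO_SPLINE
    L: float = 1.0
    age_range: tuple[float, float] = (20.0, 90.0)
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ModelValidationError(f"unknown outcome {self.outcome!r}")
        if self.sex not in SEXES:
            raise ModelValidationError(f"unknown sex {self.sex!r} (use 'F'/'M')")
        if not np.isfinite(self.L):
            raise ModelValidationError("L must be finite")
        lo, hi = self.age_range
        if not lo < hi:
            raise ModelValidationError("age_range must be increasing")
        # scatter must be positive over the covered ages
        probe = np.linspace(lo, hi, 25)
        s = predict_cv(self, probe)
        if not np.all(np.isfinite(s)) or not np.all(s > 0):
            raise ModelValidationError("S(age) must be positive over age_range")

    # convenience wrappers ---------------------------------------------
    def mean(self, age, height):
        return predict_mean(self, age, height)

    def cv(self, age):
        return predict_cv(self, age)

    def sd(self, age, height):
        return predict_mean(self, age, height) * predict_cv(self, age)

    def z(self, observed, age, height):
        return z_score(self, observed, age, height)

    def lln(self, age, height, z_critical: float = DEFAULT_Z_CRITICAL):
        return lln(self, age, height, z_critical)


def _check_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} must be positive and finite")
    return arr


def predict_mean(model: LMSReferenceModel, age, height):
    """Predicted median M(age, height) in outcome units (strictly positive)."""
    age_arr = _check_positive("age", age)
    height_arr = _check_positive("height", height)
    out = np.exp(
        model.m_b0
        + model.m_b1 * np.log(height_arr)
        + model.m_b2 * np.log(age_arr)
        + spline_at(model.m_spline, age_arr)
    )
    return float(out) if np.ndim(age) == 0 and np.ndim(height) == 0 else out


def predict_cv(model: LMSReferenceModel, age):
    """Predicted coefficient of variation S(age) (dimensionless, positive)."""
    age_arr = _check_positive("age", age)
    out = np.exp(
        model.s_b0 + model.s_b1 * np.log(age_arr) + spline_at(model.s_spline, age_arr)
    )
    return float(out) if np.ndim(age) == 0 else out


def z_score(model: LMSReferenceModel, observed, age, height):
    """Z-score of an observed value under the model.

    For ``L = 1`` this is the linear form ``(observed - M) / (M * S)``:
    the deviation from the predicted mean divided by the predicted standard
    deviation ``SD = M * S`` (CV convention).  For general ``L`` the
    Box–Cox form ``((observed/M)**L - 1) / (L * S)`` is used, which reduces
    to the linear form at ``L = 1``.
    """
    obs = _check_positive("observed", observed)
    m = np.asarray(predict_mean(model, age, height))
    s = np.asarray(predict_cv(model, age))
    if np.any(s == 0):
        raise DomainError("S = 0: Z-score scale undefined")
    if model.L == 1.0:
        out = (obs - m) / (m * s)
    else:
        out = ((obs / m) ** model.L - 1.0) / (model.L * s)
    if np.ndim(observed) == 0 and np.ndim(age) == 0 and np.ndim(height) == 0:
        return float(out)
    return out


def lln(model: LMSReferenceModel, age, height, z_critical: float = DEFAULT_Z_CRITICAL):
    """Lower limit of normal: the value whose Z-score equals ``z_critical``.

    For ``L = 1`` this is ``M * (1 + z_critical * S)``; the default
    ``z_critical`` of -1.6449 places the LLN at the 5th percentile.
    """
    m = np.asarray(predict_mean(model, age, height))
    s = np.asarray(predict_cv(model, age))
    if model.L == 1.0:
        out = m * (1.0 + z_critical * s)
    else:
        out = m * (1.0 + model.L * s * z_critical) ** (1.0 / model.L)
    if np.ndim(age) == 0 and np.ndim(height) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Piecewise polynomial (OLIN-style) model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolySegment:
    """One polynomial segment of a piecewise reference equation.

    ``mean_terms`` (and optionally ``sd_terms``) are sequences of
    ``(age_power, height_power, coefficient)`` triples; the segment value at
    ``(age, height)`` is ``sum(c * age**i * height**j)``.
    """

    age_interval: tuple[float, float]
    mean_terms: tuple[tuple[int, int, float], ...]
    sd_terms: tuple[tuple[int, int, float], ...] | None = None

    def _eval(self, terms, age, height):
        age = np.asarray(age, dtype=float)
        height = np.asarray(height, dtype=float)
        out = np.zeros(np.broadcast(age, height).shape)
        for i, j, c in terms:
            out = out + c * age**i * height**j
        return out

    def mean(self, age, height):
        return self._eval(self.mean_terms, age, height)

    def sd(self, age, height):
        if self.sd_terms is None:
            return None
        return self._eval(self.sd_terms, age, height)

    def dmean_dage(self, age, height):
        terms = tuple((i - 1, j, i * c) for i, j, c in self.mean_terms if i >= 1)
        return self._eval(terms, age, height)


@dataclass(frozen=True)
class PiecewisePolyModel:
    """Reference equations from smoothly merged polynomial age segments.

    Segments must abut without gaps, and the predicted mean and its first
    age-derivative must be continuous at every join (checked at construction
    to 1e-9 at a reference height).  No extrapolation is performed outside
    the covered age range.
    """

    outcome: str
    sex: str
    segments: tuple[PolySegment, ...]
    model_id: str = ""
    continuity_tol: float = 1e-9
    reference_height: float = 170.0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ModelValidationError(f"unknown outcome {self.outcome!r}")
        if self.sex not in SEXES:
            raise ModelValidationError(f"unknown sex {self.sex!r}")
        if not self.segments:
            raise ModelValidationError("piecewise model needs at least one segment")
        segs = sorted(self.segments, key=lambda s: s.age_interval[0])
        object.__setattr__(self, "segments", tuple(segs))
        for left, right in zip(segs, segs[1:]):
            a1 = left.age_interval[1]
            b0 = right.age_interval[0]
            if abs(a1 - b0) > 1e-12:
                raise ModelValidationError(
                    f"segments must abut: gap/overlap between {left.age_interval} "
                    f"and {right.age_interval}"
                )
            h = self.reference_height
            dv = abs(float(left.mean(a1, h)) - float(right.mean(a1, h)))
            dd = abs(float(left.dmean_dage(a1, h)) - float(right.dmean_dage(a1, h)))
            if dv > self.continuity_tol or dd > self.continuity_tol:
                raise ModelValidationError(
                    f"segments not smooth at age {a1}: |dvalue|={dv:.3g}, "
                    f"|dslope|={dd:.3g}"
                )

    @property
    def age_range(self) -> tuple[float, float]:
        return (self.segments[0].age_interval[0], self.segments[-1].age_interval[1])

    def _segment_for(self, age: float) -> PolySegment:
        lo, hi = self.age_range
        if age < lo or age > hi:
            raise DomainError(
                f"age {age} outside covered range [{lo}, {hi}]; "
                "piecewise models do not extrapolate"
            )
        for seg in self.segments:
            if age <= seg.age_interval[1]:
                return seg
        return self.segments[-1]

    def mean(self, age, height):
        return evaluate_piecewise(self, age, height)["mean"]

    def sd(self, age, height):
        return evaluate_piecewise(self, age, height)["sd"]

    def z(self, observed, age, height):
        res = evaluate_piecewise(self, age, height)
        if res["sd"] is None:
            raise DomainError("model has no scatter segments; Z undefined")
        return (np.asarray(observed, dtype=float) - res["mean"]) / res["sd"]

    def lln(self, age, height, z_critical: float = DEFAULT_Z_CRITICAL):
        res = evaluate_piecewise(self, age, height)
        if res["sd"] is None:
            raise DomainError("model has no scatter segments; LLN undefined")
        return res["mean"] + z_critical * res["sd"]


def evaluate_piecewise(model: PiecewisePolyModel, age, height) -> dict:
    """Evaluate a piecewise model at scalar or array age/height.

    Returns a dict with keys ``mean`` and ``sd`` (``sd`` is None when the
    model carries no scatter segments).  Ages outside the covered range
    raise :class:`DomainError`.
    """
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    height_arr = np.broadcast_to(
        np.asarray(height, dtype=float), age_arr.shape
    ).astype(float)
    means = np.empty_like(age_arr)
    has_sd = all(seg.sd_terms is not None for seg in model.segments)
    sds = np.empty_like(age_arr) if has_sd else None
    for k, (a, h) in enumerate(zip(age_arr, height_arr)):
        seg = model._segment_for(float(a))
        means[k] = seg.mean(a, h)
        if has_sd:
            sds[k] = seg.sd(a, h)
    if np.ndim(age) == 0:
        return {
            "mean": float(means[0]),
            "sd": float(sds[0]) if has_sd else None,
        }
    return {"mean": means, "sd": sds}


# ---------------------------------------------------------------------------
# Registry and cohort-level prediction
# ---------------------------------------------------------------------------


AnyModel = LMSReferenceModel | PiecewisePolyModel


class ModelRegistry(dict):
    """Mapping ``(outcome, sex) -> model`` with a human-readable name.

    Separate model objects are kept per sex; prediction dispatches on each
    subject's sex.
    """

    def __init__(self, name: str = "registry", models: Iterable[AnyModel] = ()):
        super().__init__()
        self.name = name
        for m in models:
            self.add(m)

    def add(self, model: AnyModel) -> None:
        self[(model.outcome, model.sex)] = model

    def get_model(self, outcome: str, sex: str) -> AnyModel:
        try:
            return self[(outcome, sex)]
        except KeyError:
            raise KeyError(
                f"registry {self.name!r} has no model for outcome={outcome!r}, "
                f"sex={sex!r}"
            ) from None


def predict_cohort(
    registry: ModelRegistry | AnyModel,
    cohort: pd.DataFrame,
    outcome: str,
    z_critical: float = DEFAULT_Z_CRITICAL,
) -> pd.DataFrame:
    """Per-subject predictions for one outcome over a cohort table.

    Parameters
    ----------
    registry
        A :class:`ModelRegistry` (dispatching per sex) or a single model
        applied to subjects of its own sex only.
    cohort
        DataFrame with columns ``subject_id, sex, age, height`` and the
        observed outcome column (``fev1``, ``fvc``, or for ``ratio`` the
        quotient ``fev1/fvc`` is formed).
    outcome
        One of ``"fev1"``, ``"fvc"``, ``"ratio"``.

    Returns
    -------
    DataFrame with columns ``subject_id, model_id, outcome, sex, observed,
    predicted_mean, predicted_sd, lln, residual, z, below_lln``; one row per
    subject.  Subjects with missing age or height are skipped and logged.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if outcome == "ratio":
        observed_all = cohort["fev1"].to_numpy(float) / cohort["fvc"].to_numpy(float)
    else:
        observed_all = cohort[outcome].to_numpy(float)

    usable = (
        cohort["age"].notna()
        & cohort["height"].notna()
        & np.isfinite(observed_all)
    )
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.warning("skipping %d subject(s) with missing age/height", n_skipped)

    frames = []
    for sex in SEXES:
        mask = usable & (cohort["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        if isinstance(registry, ModelRegistry):
            model = registry.get_model(outcome, sex)
        else:
            model = registry
            if model.sex != sex:
                continue
        sub = cohort.loc[mask]
        age = sub["age"].to_numpy(float)
        height = sub["height"].to_numpy(float)
        obs = observed_all[mask]
        if isinstance(model, LMSReferenceModel):
            m = predict_mean(model, age, height)
            s = predict_cv(model, age)
            sd = m * s
            z = z_score(model, obs, age, height)
            lo = lln(model, age, height, z_critical)
        else:
            res = evaluate_piecewise(model, age, height)
            m = res["mean"]
            sd = res["sd"]
            if sd is None:
                raise DomainError(
                    "piecewise model without scatter segments cannot score a cohort"
                )
            z = (obs - m) / sd
            lo = m + z_critical * sd
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sub["subject_id"].to_numpy(),
                    "model_id": model.model_id or f"{outcome}_{sex}",
                    "outcome": outcome,
                    "sex": sex,
                    "observed": obs,
                    "predicted_mean": m,
                    "predicted_sd": sd,
                    "lln": lo,
                    "residual": obs - m,
                    "z": z,
                    "below_lln": z < z_critical,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "subject_id",
                "model_id",
                "outcome",
                "sex",
                "observed",
                "predicted_mean",
                "predicted_sd",
                "lln",
                "residual",
                "z",
                "below_lln",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def export_lookup_table(
    registry: ModelRegistry,
    age_grid: Sequence[float],
    reference_heights: dict[str, float],
    z_critical: float = DEFAULT_Z_CRITICAL,
) -> pd.DataFrame:
    """Tabulate every LMS model of a registry on an age grid.

    Produces the columns ``outcome, sex, age, m_spline, s_spline, M, S, LLN``
    with ``M`` and ``LLN`` evaluated at the per-sex reference height (for
    example the sex-specific cohort mean height).  The exported table can be
    re-imported with :func:`lookup_table_to_registry` and reproduces the
    original predictions to within interpolation tolerance.
    """
    grid = np.asarray(age_grid, dtype=float)
    rows = []
    for (outcome, sex), model in sorted(registry.items()):
        if not isinstance(model, LMSReferenceModel):
            continue
        lo, hi = model.age_range
        if grid.min() < lo or grid.max() > hi:
            raise DomainError(
                f"age grid [{grid.min()}, {grid.max()}] outside model range "
                f"[{lo}, {hi}]"
            )
        h = reference_heights[sex]
        m = predict_mean(model, grid, np.full_like(grid, h))
        s = predict_cv(model, grid)
        rows.append(
            pd.DataFrame(
                {
                    "outcome": outcome,
                    "sex": sex,
                    "age": grid,
                    "m_spline": spline_at(model.m_spline, grid),
                    "s_spline": spline_at(model.s_spline, grid),
                    "M": m,
                    "S": s,
                    "LLN": lln(model, grid, np.full_like(grid, h), z_critical),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def lookup_table_to_registry(
    table: pd.DataFrame,
    coefficients: dict[tuple[str, str], dict[str, float]],
    name: str = "lookup",
) -> ModelRegistry:
    """Rebuild an LMS registry from an exported lookup table.

    ``coefficients`` supplies the scalar coefficients per (outcome, sex)
    (keys ``m_b0, m_b1, m_b2, s_b0, s_b1`` and optionally ``L``); the spline
    columns of the table become the spline lookup tables.
    """
    reg = ModelRegistry(name=name)
    for (outcome, sex), sub in table.groupby(["outcome", "sex"]):
        coefs = coefficients[(outcome, sex)]
        sub = sub.sort_values("age")
        ages = tuple(sub["age"])
        reg.add(
            LMSReferenceModel(
                outcome=outcome,
                sex=sex,
                m_b0=coefs["m_b0"],
                m_b1=coefs["m_b1"],
                m_b2=coefs["m_b2"],
                s_b0=coefs["s_b0"],
                s_b1=coefs["s_b1"],
                m_spline=SplineTable(ages, tuple(sub["m_spline"])),
                s_spline=SplineTable(ages, tuple(sub["s_spline"])),
                L=float(coefs.get("L", 1.0)),
                age_range=(min(ages), max(ages)),
                model_id=f"{name}_{outcome}_{sex}",
            )
        )
    return reg
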