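"""Fitting LMS-type reference equations to a cohort.

The estimator is a two-stage penalized scheme for the ``L = 1`` LMS model:

1. **Median stage** — weighted penalized least squares of ``log(y)`` on
   ``[1, log(height), log(age)]`` plus a cubic B-spline in age (P-spline:
   difference penalty on the spline coefficients).  The spline basis is
   projected, in-sample, onto the orthogonal complement of ``[1, log(age)]``
   so the scalar coefficients stay identified; with zero knots the stage
   reduces exactly to ordinary least squares of the log-linear model.
2. **Scatter stage** — the squared stage-1 log-residuals are regressed on
   ``[1, log(age)]`` plus an age spline on the log scale (a regularized
   working response with the exactly matching chi-square(1) log-bias
   correction applied to the intercept; see ``_DELTA2``).  The fitted
   log-scale variance ``sigma^2(age)`` is converted to the coefficient of
   variation via ``S = sqrt(exp(sigma^2) - 1)``.

The stages alternate, the scatter model feeding inverse-variance weights
back into the median stage, until the fitted curves are stable.  Finally the
intercept is recentred so the mean *linear-scale* residual
(observed - predicted) over the fitting cohort is exactly zero, matching
the normal-error (L = 1) reading of the model in which residuals average
zero on the litre scale.

The module also implements the 10-subset sampling-variability analysis:
the cohort is randomly partitioned into ten equal subsets, ten models are
refitted each leaving one subset out, and the min/max envelope of the
predicted mean and LLN over an age grid quantifies curve stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .models import (
    DEFAULT_Z_CRITICAL,
    LMSReferenceModel,
    SplineTable,
    lln as model_lln,
    predict_mean,
)

logger = logging.getLogger(__name__)

_CHISQ1_LOG_BIAS = 1.2703628454614782  # -(digamma(1/2) + log 2)
# The scatter stage uses the regularized working response
# log(r^2 + delta^2 * sigma^2) instead of log(r^2): the raw log is
# unboundedly sensitive to near-zero residuals and destabilizes the stage
# alternation.  The matching bias constant is -E[log(chi2_1 + delta^2)],
# which recovers the classic chi2_1 correction (+1.2704) as delta -> 0.
_DELTA2 = 0.01
_REG_LOG_BIAS = 1.0292983081  # -E[log(chi2_1 + 0.01)]
_MIN_CV = 1e-12


class FitError(RuntimeError):
    """Fitting failed; carries the iteration trace when available."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


class RankDeficiencyError(FitError):
    """The design matrix is rank deficient (e.g. constant height)."""


@dataclass(frozen=True)
class FitConfig:
    """Settings of the LMS fitting procedure.

    Parameters
    ----------
    n_knots
        Number of interior B-spline knots placed at equally spaced age
        quantiles; 0 disables the spline (pure log-linear model).
    log_age_basis
        Build the spline basis on ``log(age)`` instead of age.
    penalty_order
        Order of the difference penalty on spline coefficients (P-spline).
    smoothing
        ``"fixed_df"`` (default) targets ``fixed_df`` effective dimensions
        for the mean spline; ``"gcv"`` selects the penalty by generalized
        cross-validation.
    fixed_df / sigma_df
        Effective dimensions of the mean and scatter splines.  The small
        defaults (4 and 2) reflect adult cohorts of a few hundred subjects,
        which cannot support more flexibility.
    recenter_mean
        Recentre the intercept after convergence so the cohort-mean
        linear residual is exactly zero.
    """

    n_knots: int = 4
    log_age_basis: bool = False
    penalty_order: int = 2
    smoothing: str = "fixed_df"
    fixed_df: float = 4.0
    sigma_df: float = 2.0
    max_iterations: int = 200
    tolerance: float = 1e-6
    z_critical: float = DEFAULT_Z_CRITICAL
    seed: int = 0
    spline_grid_step: float = 0.5
    recenter_mean: bool = True

    def __post_init__(self) -> None:
        if self.n_knots < 0:
            raise ValueError("n_knots must be >= 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.smoothing not in ("fixed_df", "gcv"):
            raise ValueError("smoothing must be 'fixed_df' or 'gcv'")
        if self.penalty_order < 1:
            raise ValueError("penalty_order must be >= 1")


# ---------------------------------------------------------------------------
# Spline basis machinery
# ---------------------------------------------------------------------------


class _AgeSpline:
    """Cubic B-spline in (possibly log) age, projected against [1, log(age)].

    The projection makes the spline term empirically orthogonal to the
    intercept and the log-age regressor of the parametric part, so the
    scalar coefficients remain identified; the represented function is
    still a pure function of age:

        f(age) = B(age) @ beta - proj0 @ beta - (proj1 @ beta) * log(age)
    """

    degree = 3

    def __init__(self, ages: np.ndarray, n_knots: int, log_scale: bool):
        self.log_scale = log_scale
        x = np.log(ages) if log_scale else ages
        lo, hi = float(x.min()), float(x.max())
        if hi - lo <= 0:
            raise RankDeficiencyError("cannot build an age spline: constant age")
        interior = np.quantile(x, np.linspace(0, 1, n_knots + 2)[1:-1])
        t = np.concatenate(
            [np.full(self.degree + 1, lo), np.sort(interior), np.full(self.degree + 1, hi)]
        )
        self.knots = t
        self.n_basis = len(t) - self.degree - 1
        B = self._raw(ages)
        A = np.column_stack([np.ones_like(ages), np.log(ages)])
        self.proj, *_ = np.linalg.lstsq(A, B, rcond=None)  # (2, n_basis)
        Z = B - A @ self.proj
        # the projection leaves ~2 coefficient directions that map to (near)
        # zero in data space; drop them so the working design has full
        # column rank and the penalized system stays well conditioned at
        # any penalty weight
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        keep = evals > 1e-9 * evals.max()
        self.reduction = evecs[:, keep]  # (n_basis, n_effective)
        self.Z = Z @ self.reduction

    def _raw(self, ages: np.ndarray) -> np.ndarray:
        x = np.log(ages) if self.log_scale else np.asarray(ages, float)
        x = np.clip(x, self.knots[0], self.knots[-1])
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def function(self, beta: np.ndarray):
        """Return f(age) implied by (reduced) spline coefficients ``beta``."""
        gamma = self.reduction @ beta

        def f(ages: np.ndarray) -> np.ndarray:
            ages = np.asarray(ages, float)
            B = self._raw(ages)
            a0, a1 = self.proj @ gamma
            return B @ gamma - a0 - a1 * np.log(ages)

        return f

    def penalty(self, order: int) -> np.ndarray:
        D = np.diff(np.eye(self.n_basis), n=order, axis=0)
        return self.reduction.T @ (D.T @ D) @ self.reduction


def _penalized_solve(
    Xu: np.ndarray,
    Z: np.ndarray | None,
    y: np.ndarray,
    w: np.ndarray,
    P: np.ndarray | None,
    lam: float,
):
    """Weighted penalized LS solve; returns (coefs, spline coefs, edf)."""
    if Z is None or Z.shape[1] == 0:
        XtW = Xu.T * w
        XtWX = XtW @ Xu
        beta = np.linalg.solve(XtWX, XtW @ y)
        return beta, np.zeros(0), float(Xu.shape[1])
    X = np.hstack([Xu, Z])
    p_u = Xu.shape[1]
    XtW = X.T * w
    XtWX = XtW @ X
    Pen = np.zeros_like(XtWX)
    # tiny ridge for numerical safety only; the reduced basis is already
    # full column rank
    ridge = 1e-9 * float(np.mean(np.diag(XtWX[p_u:, p_u:])) + 1e-300)
    Pen[p_u:, p_u:] = lam * P + ridge * np.eye(Z.shape[1])
    M = XtWX + Pen
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        Minv = np.linalg.pinv(M)  # extreme penalties: minimum-norm solution
    beta = Minv @ (XtW @ y)
    edf = float(np.trace(Minv @ XtWX))
    return beta[:p_u], beta[p_u:], edf


def _select_lambda(
    Xu: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    P: np.ndarray,
    smoothing: str,
    target_df: float,
) -> float:
    """Choose the penalty weight by spline-df bisection or GCV."""
    n, p_u = Xu.shape
    max_spline_df = Z.shape[1]

    def spline_df(loglam: float) -> float:
        _, _, edf = _penalized_solve(Xu, Z, y, w, P, 10.0**loglam)
        return edf - p_u

    if smoothing == "fixed_df":
        target = min(target_df, max_spline_df - 0.5)
        lo, hi = -8.0, 9.0
        if spline_df(hi) > target:
            return 10.0**hi
        if spline_df(lo) < target:
            return 10.0**lo
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if spline_df(mid) > target:
                lo = mid
            else:
                hi = mid
        return 10.0 ** (0.5 * (lo + hi))

    best = (np.inf, 0.0)
    for loglam in np.linspace(-4, 8, 25):
        bu, bz, edf = _penalized_solve(Xu, Z, y, w, P, 10.0**loglam)
        resid = y - Xu @ bu - Z @ bz
        rss = float(np.sum(w * resid**2))
        gcv = n * rss / (n - edf) ** 2
        if gcv < best[0]:
            best = (gcv, loglam)
    return 10.0 ** best[1]


# ---------------------------------------------------------------------------
# Main fit
# ---------------------------------------------------------------------------


def _cohort_arrays(cohort: pd.DataFrame, outcome: str, sex: str):
    sub = cohort.loc[cohort["sex"] == sex]
    age = sub["age"].to_numpy(float)
    height = sub["height"].to_numpy(float)
    if outcome == "ratio":
        y = sub["fev1"].to_numpy(float) / sub["fvc"].to_numpy(float)
    else:
        y = sub[outcome].to_numpy(float)
    return age, height, y


def fit_lms(
    cohort: pd.DataFrame,
    outcome: str,
    sex: str,
    config: FitConfig | None = None,
) -> LMSReferenceModel:
    """Fit an ``L = 1`` LMS reference model to one outcome and sex.

    Returns an :class:`LMSReferenceModel` whose spline terms are stored as
    age-indexed lookup tables on a fine grid over the cohort's age range.
    Raises :class:`FitError` on non-convergence (with the iteration trace
    attached) and :class:`RankDeficiencyError` on singular designs.
    """
    if config is None:
        config = FitConfig()
    age, height, y = _cohort_arrays(cohort, outcome, sex)
    n = len(y)
    if n < 30:
        raise FitError(f"need >= 30 subjects of sex {sex!r} after screening, got {n}")
    if np.any(y <= 0) or np.any(~np.isfinite(y)):
        raise FitError("all outcome values must be positive and finite")

    ln_y = np.log(y)
    Xu = np.column_stack([np.ones(n), np.log(height), np.log(age)])
    if np.linalg.matrix_rank(Xu) < 3:
        raise RankDeficiencyError(
            "design matrix [1, log(height), log(age)] is rank deficient"
        )

    use_spline = config.n_knots > 0
    if use_spline:
        spl = _AgeSpline(age, config.n_knots, config.log_age_basis)
        P = spl.penalty(config.penalty_order)
        Z = spl.Z
    else:
        spl = None
        P = None
        Z = None

    w = np.ones(n)
    state = None
    trace: list[dict] = []
    m_coef = np.zeros(3)
    m_beta = np.zeros(0)
    log_sig2_prev = None
    step = 0.5
    prev_change = np.inf
    for iteration in range(config.max_iterations):
        # --- stage 1: median model on the log scale
        if use_spline:
            # GCV's discrete grid search is frozen after the first pass:
            # re-selection under evolving weights jumps between grid points
            # and prevents a fixed point
            if config.smoothing == "gcv" and iteration > 0:
                lam = trace[0]["lambda"]
            else:
                lam = _select_lambda(
                    Xu, Z, ln_y, w, P, config.smoothing, config.fixed_df
                )
            m_coef, m_beta, edf = _penalized_solve(Xu, Z, ln_y, w, P, lam)
            fitted = Xu @ m_coef + Z @ m_beta
        else:
            m_coef, m_beta, edf = _penalized_solve(Xu, None, ln_y, w, None, 0.0)
            fitted = Xu @ m_coef
        resid = ln_y - fitted

        # --- stage 2: scatter model from squared log-residuals
        if log_sig2_prev is None:
            sig2_work = np.full(n, max(float(np.var(resid)), 1e-300))
        else:
            sig2_work = np.exp(log_sig2_prev)
        v = np.log(resid**2 + _DELTA2 * sig2_work)
        if use_spline:
            lam_s = _select_lambda(
                Xu[:, [0, 2]], Z, v, np.ones(n), P, "fixed_df", config.sigma_df
            )
            s_coef, s_beta, _ = _penalized_solve(
                Xu[:, [0, 2]], Z, v, np.ones(n), P, lam_s
            )
            s_fun = spl.function(s_beta)

            def sig2_fun(a, s_coef=s_coef, s_fun=s_fun):
                a = np.asarray(a, float)
                return np.exp(
                    s_coef[0] + _REG_LOG_BIAS + s_coef[1] * np.log(a) + s_fun(a)
                )

        else:
            s_coef, _, _ = _penalized_solve(Xu[:, [0, 2]], None, v, np.ones(n), None, 0.0)

            def sig2_fun(a, s_coef=s_coef):
                a = np.asarray(a, float)
                return np.exp(s_coef[0] + _REG_LOG_BIAS + s_coef[1] * np.log(a))

        # damped update of the working variance: a partial log-scale step
        # suppresses the period-2 oscillation the raw alternation of the
        # two stages can fall into; the step shrinks whenever progress
        # stalls (the log(r^2) working response is hypersensitive to
        # near-zero residuals, which can push the loop gain above 1)
        log_sig2 = np.log(np.clip(sig2_fun(age), 1e-300, None))
        if log_sig2_prev is not None:
            log_sig2 = (1.0 - step) * log_sig2_prev + step * log_sig2
        if use_spline:
            # inverse-variance weights feed back into the median stage; in
            # the zero-knot configuration the median stage deliberately
            # stays the plain (unweighted) log-linear least-squares
            # estimator, the model's brute-force-checkable baseline
            w = 1.0 / np.clip(np.exp(log_sig2), 1e-10, None)
            w = w / w.mean()

        # convergence is judged on the fitted curves (log-mean and damped
        # log-variance at the data points): the raw log(r^2) working
        # response makes individual scatter coefficients hypersensitive to
        # near-zero residuals, while the fitted functions are stable
        if state is not None:
            change = max(
                float(np.max(np.abs(fitted - state))),
                float(np.max(np.abs(log_sig2 - log_sig2_prev))),
            )
        else:
            change = np.inf
        trace.append(
            {
                "iteration": iteration,
                "max_rel_change": change,
                "edf": edf,
                "step": step,
                "lambda": lam if use_spline else 0.0,
            }
        )
        if change > 2.0 * prev_change:
            step = max(step / 2.0, 0.1)
        prev_change = change
        state = fitted
        log_sig2_prev = log_sig2
        if change < config.tolerance:
            break
    else:
        raise FitError(
            f"fit did not converge in {config.max_iterations} iterations "
            f"(last relative change {trace[-1]['max_rel_change']:.3g})",
            trace,
        )

    # --- assemble the model on an age grid
    lo, hi = float(age.min()), float(age.max())
    grid = np.arange(lo, hi, config.spline_grid_step)
    grid = np.unique(np.append(grid, hi))

    if use_spline:
        m_fun = spl.function(m_beta)
        m_spline = SplineTable(tuple(grid), tuple(m_fun(grid)))
    else:
        m_spline = SplineTable()

    sig2_grid = sig2_fun(grid)
    S_grid = np.maximum(np.sqrt(np.expm1(sig2_grid)), _MIN_CV)
    ln_S = np.log(S_grid)
    A_grid = np.column_stack([np.ones_like(grid), np.log(grid)])
    s_lin, *_ = np.linalg.lstsq(A_grid, ln_S, rcond=None)
    s_resid = ln_S - A_grid @ s_lin
    s_spline = (
        SplineTable(tuple(grid), tuple(s_resid))
        if np.max(np.abs(s_resid)) > 1e-12
        else SplineTable()
    )

    model = LMSReferenceModel(
        outcome=outcome,
        sex=sex,
        m_b0=float(m_coef[0]),
        m_b1=float(m_coef[1]),
        m_b2=float(m_coef[2]),
        s_b0=float(s_lin[0]),
        s_b1=float(s_lin[1]),
        m_spline=m_spline,
        s_spline=s_spline,
        age_range=(lo, hi),
        model_id=f"rlms_{outcome}_{sex}",
    )

    if config.recenter_mean:
        # shift the intercept so the mean linear residual vanishes exactly
        m_hat = np.asarray(predict_mean(model, age, height))
        shift = float(np.log(y.mean() / m_hat.mean()))
        model = replace(model, m_b0=model.m_b0 + shift)
    return model


def fit_registry(
    cohort: pd.DataFrame,
    config: FitConfig | None = None,
    outcomes: Sequence[str] = ("fev1", "fvc", "ratio"),
    name: str = "rlms",
):
    """Fit models for every outcome and sex present in the cohort."""
    from .models import ModelRegistry

    reg = ModelRegistry(name=name)
    for sex in ("F", "M"):
        if not (cohort["sex"] == sex).any():
            continue
        for outcome in outcomes:
            reg.add(fit_lms(cohort, outcome, sex, config))
    return reg


# ---------------------------------------------------------------------------
# Subset sampling variability
# ---------------------------------------------------------------------------


def partition_subsets(
    cohort: pd.DataFrame, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Randomly partition subject ids into ``k`` disjoint subsets.

    Subset sizes differ by at most one.  The partition is stratified by sex
    and age tertile so every leave-one-out refit spans the age range, and
    is deterministic under ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(cohort) < k:
        raise ValueError(f"cohort of {len(cohort)} cannot form {k} subsets")
    rng = np.random.default_rng(seed)
    df = cohort[["subject_id", "sex", "age"]].copy()
    tert = df["age"].quantile([1 / 3, 2 / 3]).to_numpy()
    df["stratum"] = df["sex"].astype(str) + np.digitize(df["age"], tert).astype(str)
    subsets: list[list] = [[] for _ in range(k)]
    cursor = int(rng.integers(k))
    for _, grp in df.sort_values(["stratum", "subject_id"]).groupby(
        "stratum", sort=True
    ):
        ids = grp["subject_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        for sid in ids:
            subsets[cursor % k].append(sid)
            cursor += 1
    return [np.asarray(sorted(s)) for s in subsets]


@dataclass
class SubsetVariabilityResult:
    """Envelope of the leave-one-subset-out refits over an age grid.

    ``table`` has columns ``age, mean_lo, mean_hi, mean_full, lln_lo,
    lln_hi, lln_full``; ``reference_height`` is the sex mean height the
    curves were evaluated at.
    """

    outcome: str
    sex: str
    reference_height: float
    table: pd.DataFrame
    models: list[LMSReferenceModel]
    full_model: LMSReferenceModel

    def envelope_width(self, age: float, which: str = "mean") -> float:
        row = self.table.iloc[(self.table["age"] - age).abs().argmin()]
        return float(row[f"{which}_hi"] - row[f"{which}_lo"])


def subset_variability(
    cohort: pd.DataFrame,
    outcome: str,
    sex: str,
    config: FitConfig | None = None,
    k: int = 10,
    age_grid: np.ndarray | None = None,
) -> SubsetVariabilityResult:
    """Quantify sampling variability by the k-subset leave-one-out protocol.

    The cohort is partitioned into ``k`` equal subsets; ``k`` models are
    fitted, each excluding one subset; predicted mean and LLN are evaluated
    on an age grid at the sex-specific mean height; the per-age min/max
    envelope across the refits is returned together with the full-cohort
    model.
    """
    if config is None:
        config = FitConfig()
    subsets = partition_subsets(cohort, k=k, seed=config.seed)
    full_model = fit_lms(cohort, outcome, sex, config)
    ref_height = float(cohort.loc[cohort["sex"] == sex, "height"].mean())

    models = []
    for i, left_out in enumerate(subsets):
        subset_cohort = cohort.loc[~cohort["subject_id"].isin(left_out)]
        try:
            models.append(fit_lms(subset_cohort, outcome, sex, config))
        except FitError as exc:
            raise FitError(f"refit excluding subset {i} failed: {exc}") from exc

    lo, hi = full_model.age_range
    if age_grid is None:
        age_grid = np.linspace(lo, hi, 71)
    age_grid = np.asarray(age_grid, float)
    h = np.full_like(age_grid, ref_height)

    means = np.stack([np.asarray(predict_mean(m, age_grid, h)) for m in models])
    llns = np.stack(
        [np.asarray(model_lln(m, age_grid, h, config.z_critical)) for m in models]
    )
    mean_full = np.asarray(predict_mean(full_model, age_grid, h))
    lln_full = np.asarray(model_lln(full_model, age_grid, h, config.z_critical))

    table = pd.DataFrame(
        {
            "age": age_grid,
            "mean_lo": means.min(axis=0),
            "mean_hi": means.max(axis=0),
            "mean_full": mean_full,
            "lln_lo": llns.min(axis=0),
            "lln_hi": llns.max(axis=0),
            "lln_full": lln_full,
        }
    )
    outside = (table["mean_full"] < table["mean_lo"] - 1e-9) | (
        table["mean_full"] > table["mean_hi"] + 1e-9
    )
    if outside.any():
        logger.info(
            "full-model mean outside the subset envelope at %d/%d grid ages",
            int(outside.sum()),
            len(table),
        )
    return SubsetVariabilityResult(
        outcome=outcome,
        sex=sex,
        reference_height=ref_height,
        table=table,
        models=models,
        full_model=full_model,
    )
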