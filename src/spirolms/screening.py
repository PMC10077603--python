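"""Clinical LLN screening of a cohort before reference-curve fitting.

Airway obstruction is defined as FEV1/FVC below the lower limit of normal
of the ratio; small FVC as FVC below the LLN of FVC.  Subjects flagged by
either criterion are excluded from the cohort used for fitting, mirroring
the clinical pre-screening of a reference population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .models import DEFAULT_Z_CRITICAL, ModelRegistry, predict_cohort

logger = logging.getLogger(__name__)

FLAG_COLUMNS = ["subject_id", "ratio_value", "obstruction", "small_fvc", "excluded"]


@dataclass(frozen=True)
class ScreeningSummary:
    """Counts of flagged subjects by sex and flag type."""

    n_total: int
    n_excluded: int
    by_sex: dict


def screen_cohort(
    cohort: pd.DataFrame,
    reference: ModelRegistry,
    z_critical: float = DEFAULT_Z_CRITICAL,
) -> tuple[pd.DataFrame, pd.DataFrame, ScreeningSummary]:
    """Flag obstructive / small-FVC subjects and return the screened cohort.

    Parameters
    ----------
    cohort
        Cohort table with ``subject_id, sex, age, height, fev1, fvc``.
    reference
        Registry providing ``ratio`` and ``fvc`` models for both sexes
        present in the cohort (screening is performed against established
        reference values, e.g. the fixture truth registry).
    z_critical
        Z threshold of the LLN (default -1.6449, the 5th percentile).

    Returns
    -------
    flags : DataFrame
        Columns ``subject_id, ratio_value, obstruction, small_fvc,
        excluded``; ``excluded`` is ``obstruction OR small_fvc``.
    screened : DataFrame
        The input cohort without excluded subjects.
    summary : ScreeningSummary
    """
    for sex in cohort["sex"].unique():
        for outcome in ("ratio", "fvc"):
            if (outcome, sex) not in reference:
                raise KeyError(
                    f"screening reference {reference.name!r} lacks a "
                    f"{outcome!r} model for sex {sex!r}"
                )

    ratio_pred = predict_cohort(reference, cohort, "ratio", z_critical)
    fvc_pred = predict_cohort(reference, cohort, "fvc", z_critical)
    ratio_flag = ratio_pred.set_index("subject_id")["below_lln"]
    fvc_flag = fvc_pred.set_index("subject_id")["below_lln"]
    ratio_value = ratio_pred.set_index("subject_id")["observed"]

    ids = cohort["subject_id"]
    flags = pd.DataFrame(
        {
            "subject_id": ids.to_numpy(),
            "ratio_value": ratio_value.reindex(ids).to_numpy(),
            "obstruction": ratio_flag.reindex(ids).fillna(False).to_numpy(bool),
            "small_fvc": fvc_flag.reindex(ids).fillna(False).to_numpy(bool),
        }
    )
    flags["excluded"] = flags["obstruction"] | flags["small_fvc"]

    screened = cohort.loc[~flags["excluded"].to_numpy()].reset_index(drop=True)

    by_sex = {}
    merged = flags.merge(cohort[["subject_id", "sex"]], on="subject_id")
    for sex, grp in merged.groupby("sex"):
        by_sex[sex] = {
            "obstruction": int(grp["obstruction"].sum()),
            "small_fvc": int(grp["small_fvc"].sum()),
            "excluded": int(grp["excluded"].sum()),
        }
    summary = ScreeningSummary(
        n_total=len(cohort), n_excluded=int(flags["excluded"].sum()), by_sex=by_sex
    )
    logger.info(
        "screening: %d/%d subjects excluded (%s)",
        summary.n_excluded,
        summary.n_total,
        by_sex,
    )
    return flags[FLAG_COLUMNS], screened, summary
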