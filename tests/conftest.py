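"""Shared fixtures: truth models, synthetic cohorts, piecewise fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spirolms import (
    GeneratorConfig,
    LMSReferenceModel,
    ModelRegistry,
    PiecewisePolyModel,
    PolySegment,
    default_truth_registry,
    generate_cohort,
)
from spirolms.cohort import _TRUTH_M


@pytest.fixture(scope="session")
def truth_registry() -> ModelRegistry:
    return default_truth_registry()


@pytest.fixture(scope="session")
def healthy_cohort() -> pd.DataFrame:
    """Default-structure cohort without injected pathology (seed 42)."""
    return generate_cohort(GeneratorConfig(seed=42, pathology_fraction=0.0))


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Default cohort including the 6% pathology fraction (seed 7)."""
    return generate_cohort(GeneratorConfig(seed=7))


def make_constant_s_registry(s_value: float, name: str = "truth_flat_s") -> ModelRegistry:
    """Truth registry with age-constant scatter for all outcomes."""
    reg = ModelRegistry(name=name)
    for sex in ("F", "M"):
        for outcome in ("fev1", "fvc"):
            b0, b1, b2 = _TRUTH_M[(outcome, sex)]
            reg.add(
                LMSReferenceModel(
                    outcome=outcome, sex=sex, m_b0=b0, m_b1=b1, m_b2=b2,
                    s_b0=float(np.log(s_value)), s_b1=0.0,
                    model_id=f"{name}_{outcome}_{sex}",
                )
            )
        fe, fv = _TRUTH_M[("fev1", sex)], _TRUTH_M[("fvc", sex)]
        reg.add(
            LMSReferenceModel(
                outcome="ratio", sex=sex,
                m_b0=fe[0] - fv[0], m_b1=fe[1] - fv[1], m_b2=fe[2] - fv[2],
                s_b0=float(np.log(max(s_value * 0.57, 1e-12))), s_b1=0.0,
                model_id=f"{name}_ratio_{sex}",
            )
        )
    return reg


def make_smooth_piecewise(outcome: str = "fev1", sex: str = "M") -> PiecewisePolyModel:
    """Two cubic segments joined with continuous value and slope at age 50.

    The right segment adds a pure (age-50)^2 term to the left polynomial,
    so the join is smooth by construction.
    """
    left = PolySegment(
        age_interval=(20.0, 50.0),
        mean_terms=((0, 0, 0.5), (1, 0, 0.02), (2, 0, -3e-4), (3, 0, 1e-6), (0, 1, 0.01)),
        sd_terms=((0, 0, 0.4),),
    )
    # (age-50)^2 = age^2 - 100*age + 2500
    q = -2e-4
    right = PolySegment(
        age_interval=(50.0, 90.0),
        mean_terms=(
            (0, 0, 0.5 + q * 2500.0),
            (1, 0, 0.02 - q * 100.0),
            (2, 0, -3e-4 + q),
            (3, 0, 1e-6),
            (0, 1, 0.01),
        ),
        sd_terms=((0, 0, 0.4),),
    )
    return PiecewisePolyModel(
        outcome=outcome, sex=sex, segments=(left, right), model_id="olin_like"
    )
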