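"""Readers and writers for cohort CSVs, model YAMLs and lookup tables.

All text outputs carry a provenance header (package version, seed, config
hash) as ``#``-prefixed comment lines (CSV) or a ``provenance`` mapping
(YAML/JSON), so byte-identical artifacts imply identical configurations.
CSV dialect: comma separator, ``.`` decimal point, UTF-8, header required.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import COHORT_COLUMNS
from .models import (
    LMSReferenceModel,
    ModelRegistry,
    ModelValidationError,
    PiecewisePolyModel,
    PolySegment,
    SplineTable,
)

logger = logging.getLogger(__name__)

SMOKING_VALUES = {"never", "current", "former", "unknown"}


class SchemaError(ValueError):
    """A file does not match the declared schema."""


def provenance_dict(seed: int | None = None, config: dict | None = None) -> dict:
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return {
        "tool": "spirolms",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest()[:16],
    }


def _provenance_lines(prov: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in prov.items())


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Apply per-subject invariants; return (valid rows, rejection messages)."""
    problems = []
    keep = np.ones(len(df), dtype=bool)
    num = {c: pd.to_numeric(df[c], errors="coerce") for c in
           ("age", "height", "weight", "fev1", "fvc")}

    def reject(mask, reason):
        for row in df.index[mask & keep]:
            problems.append(f"row {row + 2}: {reason}")  # +2: header + 1-based
        keep[np.asarray(mask)] = False

    reject(~df["sex"].isin(["F", "M"]).to_numpy(), "sex must be 'F' or 'M'")
    for c, v in num.items():
        reject(v.isna().to_numpy(), f"{c} is not numeric")
    reject(((num["age"] < 18) | (num["age"] > 95)).fillna(False).to_numpy(),
           "age outside [18, 95]")
    reject(((num["height"] < 130) | (num["height"] > 220)).fillna(False).to_numpy(),
           "height outside [130, 220] cm")
    reject((num["fev1"] <= 0).fillna(False).to_numpy(), "fev1 must be > 0")
    reject((num["fvc"] <= 0).fillna(False).to_numpy(), "fvc must be > 0")
    reject((num["fev1"] > num["fvc"]).fillna(False).to_numpy(),
           "fev1 > fvc (ratio must be in (0, 1])")
    if "smoking" in df:
        reject(~df["smoking"].isin(SMOKING_VALUES).to_numpy(),
               "smoking must be never/current/former/unknown")
    out = df.loc[keep].copy()
    for c in num:
        out[c] = pd.to_numeric(out[c])
    return out.reset_index(drop=True), problems


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Rows violating the subject invariants (age in [18, 95], height in
    [130, 220] cm, positive volumes, fev1 <= fvc, known codes) are rejected
    with row-numbered log messages; accepted/rejected counts are logged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "smoking"]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if "smoking" not in df.columns:
        df["smoking"] = "unknown"
    if len(df) == 0:
        logger.warning("%s: empty cohort (header only)", path)
        return df[COHORT_COLUMNS]
    valid, problems = _validate_rows(df)
    for msg in problems:
        logger.warning("%s: rejected %s", path, msg)
    logger.info("%s: accepted %d row(s), rejected %d", path, len(valid), len(problems))
    return valid[COHORT_COLUMNS]


def write_cohort(
    cohort: pd.DataFrame, path: str | Path, seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write a cohort CSV with a provenance header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(provenance_dict(seed, config)))
        cohort[COHORT_COLUMNS].to_csv(fh, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Model YAML
# ---------------------------------------------------------------------------


def _spline_to_obj(table: SplineTable) -> dict | None:
    if table.is_zero:
        return None
    return {
        "interpolation": table.interpolation,
        "knots": [[float(a), float(v)] for a, v in zip(table.ages, table.values)],
    }


def _spline_from_obj(obj: dict | str | None) -> SplineTable:
    if obj is None:
        return SplineTable()
    if isinstance(obj, str):  # referenced CSV with columns age,value
        csv = pd.read_csv(obj, comment="#")
        if not {"age", "value"} <= set(csv.columns):
            raise SchemaError(f"spline CSV {obj} must have columns age,value")
        return SplineTable(tuple(csv["age"]), tuple(csv["value"]))
    knots = obj.get("knots", [])
    ages = tuple(float(k[0]) for k in knots)
    if len(set(ages)) != len(ages):
        raise ModelValidationError("spline table has duplicate ages")
    try:
        return SplineTable(
            ages,
            tuple(float(k[1]) for k in knots),
            obj.get("interpolation", "pchip"),
        )
    except ModelValidationError:
        raise
    except Exception as exc:
        raise SchemaError(f"malformed spline table: {exc}") from exc


def write_model(
    model: LMSReferenceModel | PiecewisePolyModel,
    path: str | Path,
    seed: int | None = None,
) -> None:
    """Serialize a model to YAML (with provenance)."""
    if isinstance(model, LMSReferenceModel):
        doc = {
            "model_type": "lms",
            "outcome": model.outcome,
            "sex": model.sex,
            "model_id": model.model_id,
            "m": {"b0": model.m_b0, "b1": model.m_b1, "b2": model.m_b2},
            "s": {"b0": model.s_b0, "b1": model.s_b1},
            "L": model.L,
            "age_range": list(model.age_range),
            "m_spline": _spline_to_obj(model.m_spline),
            "s_spline": _spline_to_obj(model.s_spline),
        }
    else:
        doc = {
            "model_type": "piecewise",
            "outcome": model.outcome,
            "sex": model.sex,
            "model_id": model.model_id,
            "reference_height": model.reference_height,
            "segments": [
                {
                    "age_interval": list(seg.age_interval),
                    "mean_terms": [list(t) for t in seg.mean_terms],
                    "sd_terms": (
                        [list(t) for t in seg.sd_terms]
                        if seg.sd_terms is not None
                        else None
                    ),
                }
                for seg in model.segments
            ],
        }
    doc["provenance"] = provenance_dict(seed, {"model_id": model.model_id})
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_model(path: str | Path) -> LMSReferenceModel | PiecewisePolyModel:
    """Load and validate a model YAML; ``L`` defaults to 1 when absent."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "model_type" not in doc:
        raise SchemaError(f"{path}: missing model_type")
    kind = doc["model_type"]
    try:
        if kind == "lms":
            return LMSReferenceModel(
                outcome=doc["outcome"],
                sex=doc["sex"],
                m_b0=float(doc["m"]["b0"]),
                m_b1=float(doc["m"]["b1"]),
                m_b2=float(doc["m"]["b2"]),
                s_b0=float(doc["s"]["b0"]),
                s_b1=float(doc["s"]["b1"]),
                m_spline=_spline_from_obj(doc.get("m_spline")),
                s_spline=_spline_from_obj(doc.get("s_spline")),
                L=float(doc.get("L", 1.0)),
                age_range=tuple(doc.get("age_range", (20.0, 90.0))),
                model_id=doc.get("model_id", path.stem),
            )
        if kind == "piecewise":
            segments = tuple(
                PolySegment(
                    age_interval=tuple(seg["age_interval"]),
                    mean_terms=tuple(
                        (int(i), int(j), float(c)) for i, j, c in seg["mean_terms"]
                    ),
                    sd_terms=(
                        tuple((int(i), int(j), float(c)) for i, j, c in seg["sd_terms"])
                        if seg.get("sd_terms") is not None
                        else None
                    ),
                )
                for seg in doc["segments"]
            )
            return PiecewisePolyModel(
                outcome=doc["outcome"],
                sex=doc["sex"],
                segments=segments,
                model_id=doc.get("model_id", path.stem),
                reference_height=float(doc.get("reference_height", 170.0)),
            )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed {kind} model: {exc}") from exc
    raise SchemaError(f"{path}: unknown model_type {kind!r}")


def read_registry(directory: str | Path, name: str | None = None) -> ModelRegistry:
    """Load every ``*.yaml`` model file in a directory into a registry."""
    directory = Path(directory)
    files = sorted(directory.glob("*.yaml")) + sorted(directory.glob("*.yml"))
    if not files:
        raise SchemaError(f"no model YAML files in {directory}")
    reg = ModelRegistry(name=name or directory.name)
    for f in files:
        reg.add(read_model(f))
    return reg


def write_registry(
    registry: ModelRegistry, directory: str | Path, seed: int | None = None
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (outcome, sex), model in sorted(registry.items()):
        write_model(model, directory / f"{registry.name}_{outcome}_{sex}.yaml", seed)


# ---------------------------------------------------------------------------
# Lookup-table CSV
# ---------------------------------------------------------------------------


def write_lookup_table(
    table: pd.DataFrame, path: str | Path, seed: int | None = None,
    config: dict | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(provenance_dict(seed, config)))
        table.to_csv(fh, index=False, lineterminator="\n", float_format="%.6f")


def read_lookup_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"outcome", "sex", "age", "m_spline", "s_spline", "M", "S", "LLN"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: lookup table missing columns "
                          f"{sorted(required - set(df.columns))}")
    return df
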