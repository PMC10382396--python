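"""CSV readers/writers for measurement tables and result tables."""

from __future__ import annotations

import datetime
import logging
import math
from pathlib import Path
from typing import List, Sequence, Union

import pandas as pd

from .errors import ValidationError
from .types import CentreTestResult, ConsensusOutcome, MeasurementRecord, parse_sex

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "centre_id", "specimen_id", "sex", "body_weight",
    "batch", "strain", "trait_id", "value",
]
RESULT_COLUMNS = [
    "centre_id", "trait_id", "n_male", "n_female",
    "effect_size", "effect_se", "p_value", "q_value",
]
SCORE_COLUMNS = [
    "trait_id", "m_bar", "penalty", "score", "neglog_score",
    "decision", "direction", "mean_effect_size",
]

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_measurements(path: PathLike) -> List[MeasurementRecord]:
    """Read a per-animal measurement CSV into validated records.

    Rows with a missing body_weight load with the field unset (they are
    excluded from model fitting later, with a logged count); any other
    malformed cell raises a row-numbered :class:`ValidationError`.
    """
    df = pd.read_csv(
        path,
        dtype={"centre_id": str, "specimen_id": str, "strain": str},
        float_precision="round_trip",
    )
    _require_columns(df, [c for c in MEASUREMENT_COLUMNS if c != "strain"], path)
    if "strain" not in df.columns:
        df["strain"] = ""
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            bw = None if pd.isna(row.body_weight) else float(row.body_weight)
            value = float(row.value)
            if not math.isfinite(value):
                raise ValidationError("non-numeric value")
            records.append(
                MeasurementRecord(
                    centre_id=str(row.centre_id),
                    specimen_id=str(row.specimen_id),
                    sex=parse_sex(row.sex),
                    body_weight=bw,
                    batch=datetime.date.fromisoformat(str(row.batch)),
                    strain=str(row.strain),
                    trait_id=str(row.trait_id),
                    value=value,
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
    keys = {(r.centre_id, r.specimen_id, r.trait_id) for r in records}
    if len(keys) != len(records):
        raise ValidationError(f"{path}: duplicate (centre, specimen, trait) rows")
    return records


def write_measurements(records: Sequence[MeasurementRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "centre_id": r.centre_id, "specimen_id": r.specimen_id,
                "sex": r.sex.value, "body_weight": r.body_weight,
                "batch": r.batch.isoformat(), "strain": r.strain,
                "trait_id": r.trait_id, "value": r.value,
            }
            for r in records
        ],
        columns=MEASUREMENT_COLUMNS,
    ).to_csv(path, index=False)


def read_centre_results(path: PathLike) -> List[CentreTestResult]:
    """Read a per-centre results CSV (the entry point for users bringing their
    own per-centre statistics; the score only needs q_i and rho_i).

    A q_value column is optional: results with only p-values must go through
    ``apply_fdr`` before scoring.
    """
    df = pd.read_csv(
        path,
        dtype={"centre_id": str, "trait_id": str},
        float_precision="round_trip",
    )
    _require_columns(
        df, ["centre_id", "trait_id", "effect_size", "p_value"], path
    )
    results = []
    for i, row in df.iterrows():
        rownum = i + 2
        q = None
        if "q_value" in df.columns and not pd.isna(row["q_value"]):
            q = float(row["q_value"])
            if not 0.0 <= q <= 1.0:
                raise ValidationError(f"{path} row {rownum}: q_value {q} outside [0,1]")
        p = float(row["p_value"])
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{path} row {rownum}: p_value {p} outside [0,1]")
        try:
            results.append(
                CentreTestResult(
                    centre_id=str(row["centre_id"]),
                    trait_id=str(row["trait_id"]),
                    n_male=int(row.get("n_male", 0)),
                    n_female=int(row.get("n_female", 0)),
                    effect_size=float(row["effect_size"]),
                    effect_se=float(row.get("effect_se", 1.0)),
                    p_value=p,
                    q_value=q,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {rownum}: {exc}") from None
    keys = {(r.centre_id, r.trait_id) for r in results}
    if len(keys) != len(results):
        raise ValidationError(f"{path}: duplicate (centre, trait) rows")
    return results


def write_centre_results(results: Sequence[CentreTestResult], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "centre_id": r.centre_id, "trait_id": r.trait_id,
                "n_male": r.n_male, "n_female": r.n_female,
                "effect_size": r.effect_size, "effect_se": r.effect_se,
                "p_value": r.p_value, "q_value": r.q_value,
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    ).to_csv(path, index=False)


def write_scores(outcomes: Sequence[ConsensusOutcome], path: PathLike) -> None:
    """Write the per-trait consensus table at full precision."""
    pd.DataFrame(
        [
            {
                "trait_id": o.trait_id, "m_bar": o.m_bar, "penalty": o.penalty,
                "score": o.score, "neglog_score": o.neglog_score,
                "decision": o.decision.value, "direction": o.direction.value,
                "mean_effect_size": o.mean_effect,
            }
            for o in outcomes
        ],
        columns=SCORE_COLUMNS,
    ).to_csv(path, index=False)
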