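"""Patient-record JSON payload: the EHR-to-engine data contract.

A payload carries pseudonymous demographics, a timestamped covariate
timeline (weight, height, serum creatinine), dose events, TDM
concentrations, and an append-only audit list of user edits.  Timestamps
are ISO-8601; internally every event is converted to hours from the first
dose of the course.  Unknown fields are preserved on round trip so newer
payload producers do not lose data through this reader.

Schema version "1.0"; readers warn on newer minor versions of "1.x".
"""
from __future__ import annotations

import json
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, Field
from pydantic import ValidationError as PydanticValidationError

from .config import DEFAULT_CONFIG, RunConfig
from .course import PatientCourse, TdmObservation
from .dynamics import DoseEvent, Regimen
from .errors import ValidationError
from .models import CovariateRecord, select_model

SCHEMA_VERSION = "1.0"


class _Allow(BaseModel):
    model_config = ConfigDict(extra="allow")


class PatientInfo(_Allow):
    id: str
    sex: Optional[str] = None
    birth_date: Optional[str] = None
    chronological_age_days: Optional[float] = None
    gestational_age_weeks: Optional[float] = None
    postmenstrual_age_weeks: Optional[float] = None


class CovariateEntry(_Allow):
    time: str
    weight_kg: Optional[float] = None
    height_cm: Optional[float] = None
    serum_creatinine_mg_dl: Optional[float] = None


class DoseEntry(_Allow):
    time: str
    amount_mg: float = Field(gt=0)
    infusion_duration_h: Optional[float] = Field(default=None, gt=0)


class TdmEntry(_Allow):
    time: str
    concentration_mg_l: float = Field(gt=0)
    flag: str = "used"


class EditEntry(_Allow):
    path: str
    old: Any = None
    new: Any = None
    note: str = ""
    timestamp: str = ""


class PatientPayload(_Allow):
    schema_version: str = SCHEMA_VERSION
    patient: PatientInfo
    covariate_timeline: list[CovariateEntry]
    doses: list[DoseEntry]
    tdm: list[TdmEntry] = Field(default_factory=list)
    edits: list[EditEntry] = Field(default_factory=list)


def _parse_time(stamp: str, context: str) -> datetime:
    try:
        return datetime.fromisoformat(stamp)
    except ValueError as exc:
        raise ValidationError(f"{context}: bad ISO-8601 timestamp {stamp!r}") from exc


def _validate(payload: PatientPayload) -> None:
    problems = []
    major, _, minor = payload.schema_version.partition(".")
    if major != SCHEMA_VERSION.partition(".")[0]:
        problems.append(
            f"schema_version {payload.schema_version!r} has unsupported major version"
        )
    elif payload.schema_version != SCHEMA_VERSION:
        warnings.warn(
            f"payload schema_version {payload.schema_version} is newer than "
            f"{SCHEMA_VERSION}; reading best-effort",
            stacklevel=3,
        )
    if not payload.doses:
        problems.append("payload has no dose events")
    else:
        times = [_parse_time(d.time, f"doses[{i}]") for i, d in enumerate(payload.doses)]
        if any(b < a for a, b in zip(times, times[1:])):
            problems.append("dose times are not in chronological order")
        first = times[0]
        for i, t in enumerate(payload.tdm):
            if _parse_time(t.time, f"tdm[{i}]") < first:
                problems.append(
                    f"tdm[{i}] at {t.time} precedes the first dose at "
                    f"{payload.doses[0].time}"
                )
    if not payload.covariate_timeline:
        problems.append("payload has no covariate records")
    if problems:
        raise ValidationError("invalid payload: " + "; ".join(problems))


def read_payload(path: str | Path) -> PatientPayload:
    """Read and validate a patient payload; errors list every failing field."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"patient file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path} is not valid JSON: {exc}") from exc
    try:
        payload = PatientPayload.model_validate(raw)
    except PydanticValidationError as exc:
        fields = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ValidationError(f"invalid payload {path}: {fields}") from exc
    _validate(payload)
    return payload


def write_payload(payload: PatientPayload, path: str | Path) -> None:
    # exclude_unset keeps the round trip literal: fields the producer never
    # sent are not invented on the way out
    Path(path).write_text(
        json.dumps(payload.model_dump(mode="json", exclude_unset=True),
                   indent=2) + "\n"
    )


def edit_record(
    payload: PatientPayload,
    field_path: str,
    new_value,
    note: str = "",
    timestamp: str | None = None,
) -> PatientPayload:
    """Replace a value at a dotted path, appending an audit entry.

    Paths look like ``doses.0.amount_mg`` or ``patient.sex``.  The audit
    list is append-only: reverting an edit appends another entry.
    """
    data = payload.model_dump(mode="json")
    node = data
    parts = field_path.split(".")
    try:
        for p in parts[:-1]:
            node = node[int(p)] if isinstance(node, list) else node[p]
        leaf = parts[-1]
        key = int(leaf) if isinstance(node, list) else leaf
        old = node[key]
        node[key] = new_value
    except (KeyError, IndexError, TypeError, ValueError) as exc:
        raise ValidationError(f"invalid field path {field_path!r}") from exc
    if timestamp is None:
        timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    data.setdefault("edits", []).append(
        {"path": field_path, "old": old, "new": new_value, "note": note,
         "timestamp": timestamp}
    )
    return PatientPayload.model_validate(data)


def _hours_since(t0: datetime, stamp: str, context: str) -> float:
    return (_parse_time(stamp, context) - t0).total_seconds() / 3600.0


def to_course(
    payload: PatientPayload,
    model_id: str | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> PatientCourse:
    """Convert a payload to an analysis-ready course (hours from first dose).

    Covariate entries carry values forward: each record inherits the most
    recent weight/height/creatinine seen so far.  Ages are taken at the
    start of the course.
    """
    t0 = _parse_time(payload.doses[0].time, "doses[0]")
    p = payload.patient
    age_days = p.chronological_age_days
    if age_days is None and p.birth_date is not None:
        age_days = (t0 - _parse_time(p.birth_date, "patient.birth_date")
                    ).total_seconds() / 86400.0
    if age_days is None:
        raise ValidationError(
            "patient needs chronological_age_days or birth_date"
        )
    weight = height = creat = None
    records = []
    for i, c in enumerate(payload.covariate_timeline):
        weight = c.weight_kg if c.weight_kg is not None else weight
        height = c.height_cm if c.height_cm is not None else height
        creat = (c.serum_creatinine_mg_dl
                 if c.serum_creatinine_mg_dl is not None else creat)
        if weight is None or creat is None:
            continue  # record not yet complete enough to use
        records.append(
            CovariateRecord(
                weight_kg=weight,
                serum_creatinine_mg_dl=max(creat, config.creatinine_floor),
                chronological_age_days=age_days,
                gestational_age_weeks=p.gestational_age_weeks,
                postmenstrual_age_weeks=p.postmenstrual_age_weeks,
                height_cm=height,
                sex=p.sex,
                effective_time_h=_hours_since(t0, c.time, f"covariates[{i}]"),
            )
        )
    if not records:
        raise ValidationError(
            "covariate timeline never provides both weight and creatinine"
        )
    if model_id is None:
        model_id = select_model(
            chronological_age_days=age_days,
            gestational_age_weeks=p.gestational_age_weeks,
            postmenstrual_age_weeks=p.postmenstrual_age_weeks,
            config=config,
        )
    doses = [
        DoseEvent(
            start_time_h=_hours_since(t0, d.time, f"doses[{i}]"),
            amount_mg=d.amount_mg,
            infusion_duration_h=(d.infusion_duration_h
                                 if d.infusion_duration_h is not None
                                 else config.default_infusion_duration_h),
        )
        for i, d in enumerate(payload.doses)
    ]
    observations = [
        TdmObservation(
            time_h=_hours_since(t0, t.time, f"tdm[{i}]"),
            concentration_mg_l=t.concentration_mg_l,
            flag=t.flag,
        )
        for i, t in enumerate(payload.tdm)
    ]
    return PatientCourse(
        patient_id=p.id,
        model_id=model_id,
        covariates=records,
        doses=doses,
        observations=observations,
    )


def current_regimen(payload: PatientPayload,
                    config: RunConfig = DEFAULT_CONFIG) -> Regimen:
    """Infer the regimen in effect from the tail of the dose history."""
    course = to_course(payload, config=config)
    doses = course.doses
    last = doses[-1]
    if len(doses) >= 2:
        interval = last.start_time_h - doses[-2].start_time_h
    else:
        interval = config.intervals_h[0]
    return Regimen(last.amount_mg, interval, last.infusion_duration_h)
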