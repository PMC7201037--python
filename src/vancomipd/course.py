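"""A vancomycin treatment course: covariate timeline, doses, TDM observations.

Internal time base is hours from the first dose of the course.  Covariates
are carried forward from the most recent record at each dose or prediction
time (values before the first record use the first record), so a creatinine
drawn mid-course changes the model parameters from that point on.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .dynamics import DoseEvent, _infusion_conc
from .errors import ValidationError
from .models import (
    CovariateRecord,
    PopulationModel,
    get_model,
    realize_individual,
    typical_parameters,
)


@dataclass(frozen=True)
class TdmObservation:
    """One measured serum vancomycin concentration."""

    time_h: float
    concentration_mg_l: float
    flag: str = "used"  # or "excluded" (mirrors the tool's manual-edit ability)

    def __post_init__(self):
        if self.concentration_mg_l <= 0:
            raise ValidationError("TDM concentration must be positive")
        if self.flag not in ("used", "excluded"):
            raise ValidationError("flag must be 'used' or 'excluded'")


@dataclass
class PatientCourse:
    """One treatment course for one patient."""

    patient_id: str
    model_id: str
    covariates: list[CovariateRecord]
    doses: list[DoseEvent]
    observations: list[TdmObservation] = field(default_factory=list)
    true_eta: tuple[float, ...] | None = None  # synthetic courses only
    mic: float | None = None

    def __post_init__(self):
        if not self.covariates:
            raise ValidationError("course needs at least one covariate record")
        self.covariates = sorted(self.covariates,
                                 key=lambda c: c.effective_time_h)
        self.doses = sorted(self.doses, key=lambda d: d.start_time_h)

    def covariates_at(self, time_h: float) -> CovariateRecord:
        """Last covariate record at or before time_h (first record if none)."""
        times = [c.effective_time_h for c in self.covariates]
        i = bisect.bisect_right(times, time_h) - 1
        return self.covariates[max(i, 0)]

    @property
    def model(self) -> PopulationModel:
        return get_model(self.model_id)

    def used_observations(self) -> list[TdmObservation]:
        return [o for o in self.observations if o.flag == "used"]


def predict_course(
    course: PatientCourse,
    eta,
    times,
    config: RunConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Individual concentration prediction along a course.

    Each dose's contribution is evaluated with the model parameters implied
    by the covariates in effect at that dose's start (carried forward), so a
    mid-course creatinine change alters the kinetics of subsequent doses
    while the linear superposition stays closed-form.
    """
    model = course.model
    times = np.atleast_1d(np.asarray(times, dtype=float))
    conc = np.zeros_like(times)
    from .dynamics import disposition_terms

    for d in course.doses:
        cov = course.covariates_at(d.start_time_h)
        tv = typical_parameters(course.model_id, cov, config)
        p = realize_individual(model, tv, eta).realized
        lam, coef = disposition_terms(p.cl, p.v, p.v2, p.q)
        rate = d.amount_mg / d.infusion_duration_h
        conc = conc + _infusion_conc(
            lam, coef, rate, times - d.start_time_h, d.infusion_duration_h
        )
    return conc


def course_typical_parameters(
    course: PatientCourse,
    at_time_h: float | None = None,
    config: RunConfig = DEFAULT_CONFIG,
):
    """Typical parameters from the covariates in effect at a time (default: latest)."""
    if at_time_h is None:
        at_time_h = float("inf")
    return typical_parameters(
        course.model_id, course.covariates_at(at_time_h), config
    )


def with_observation(course: PatientCourse, obs: TdmObservation) -> PatientCourse:
    return replace(course, observations=[*course.observations, obs])
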