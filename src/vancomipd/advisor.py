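"""Decision-support layer: reference tables, dose search, empiric dosing.

The reference table evaluates the current regimen plus doses scaled by
+/-15% and +/-30% (interval unchanged), each with steady-state AUC24 and
trough and Monte-Carlo attainment probabilities.  ``find_regimen`` searches
an interval set x rounded dose grid for the regimen whose predicted metric
is closest to the middle of the requested exposure band.  Empiric starting
doses follow the institutional guideline pattern: children get 15 mg/kg
q6h/q8h (interval extended with a renal flag when Schwartz eGFR is below
75 ml/min/1.73 m^2); neonates get a model-based start from the neonatal
prior alone.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig, TargetSpec
from .dynamics import (
    ExposureSummary,
    Regimen,
    steady_state_auc24,
    steady_state_trough,
    steady_state_metrics,
)
from .errors import NoFeasibleRegimenError, ValidationError
from .estimate import PosteriorEstimate, attainment_probability
from .models import CovariateRecord, PopulationModel, get_model, typical_parameters

#: dose multipliers of the reference table, in display order
REFERENCE_MULTIPLIERS = (0.70, 0.85, 1.00, 1.15, 1.30)

SCHWARTZ_K = 0.413  # bedside Schwartz coefficient, ml/min/1.73m^2 per (cm / (mg/dL))
EGFR_REDUCED_RENAL = 75.0  # ml/min/1.73 m^2, guideline gate for lower dosing


def schwartz_egfr(height_cm: float, serum_creatinine_mg_dl: float) -> float:
    """Modified (bedside) Schwartz eGFR: 0.413 * height / SCr, ml/min/1.73 m^2."""
    if height_cm <= 0:
        raise ValidationError("height must be positive (eGFR unavailable without it)")
    if serum_creatinine_mg_dl <= 0:
        raise ValidationError("serum creatinine must be positive")
    return SCHWARTZ_K * height_cm / serum_creatinine_mg_dl


@dataclass(frozen=True)
class ReferenceRow:
    multiplier: float
    regimen: Regimen
    exposure: ExposureSummary


@dataclass(frozen=True)
class ReferenceTable:
    rows: tuple[ReferenceRow, ...]

    def row(self, multiplier: float) -> ReferenceRow:
        for r in self.rows:
            if math.isclose(r.multiplier, multiplier):
                return r
        raise KeyError(multiplier)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "multiplier": r.multiplier,
                    "dose_mg": r.regimen.dose_mg,
                    "interval_h": r.regimen.interval_h,
                    "auc24_ss": r.exposure.auc24_ss,
                    "trough_ss": r.exposure.trough_ss,
                    "p_auc24_gt_400": r.exposure.p_auc24_gt_400,
                    "p_trough_gt_20": r.exposure.p_trough_gt_20,
                }
                for r in self.rows
            ]
        )


def evaluate_custom_regimen(
    model: PopulationModel,
    posterior: PosteriorEstimate,
    regimen: Regimen,
    config: RunConfig = DEFAULT_CONFIG,
    mic: float = 1.0,
) -> ExposureSummary:
    """Predicted steady-state exposure of any user-supplied regimen."""
    point = steady_state_metrics(posterior.realized(), regimen)
    p_auc, p_trough = attainment_probability(
        model, posterior, regimen, mic=mic, config=config
    )
    return replace(point, p_auc24_gt_400=p_auc, p_trough_gt_20=p_trough)


def reference_table(
    model: PopulationModel,
    posterior: PosteriorEstimate,
    current_regimen: Regimen,
    config: RunConfig = DEFAULT_CONFIG,
    mic: float = 1.0,
) -> ReferenceTable:
    """Exposure of the current regimen and doses at +/-15% and +/-30%."""
    rows = []
    for m in REFERENCE_MULTIPLIERS:
        reg = replace(current_regimen, dose_mg=current_regimen.dose_mg * m)
        rows.append(
            ReferenceRow(
                multiplier=m,
                regimen=reg,
                exposure=evaluate_custom_regimen(model, posterior, reg,
                                                 config, mic),
            )
        )
    return ReferenceTable(rows=tuple(rows))


@dataclass(frozen=True)
class SearchConstraints:
    """Grid over which find_regimen searches."""

    intervals_h: tuple[float, ...] = (6.0, 8.0, 12.0, 24.0)
    dose_increment_mg: float = 25.0
    min_dose_mg: float | None = None  # defaults to one increment
    max_dose_mg: float = 4000.0
    infusion_duration_h: float = 1.0


def _predicted_metric(posterior: PosteriorEstimate, doses: np.ndarray,
                      interval: float, target: TargetSpec,
                      infusion_duration: float) -> np.ndarray:
    p = posterior.realized()
    if target.metric == "auc24_over_mic":
        return (24.0 / interval) * doses / p.cl / target.mic
    troughs = np.empty_like(doses)
    for i, d in enumerate(doses):
        reg = Regimen(d, interval, infusion_duration)
        troughs[i] = steady_state_trough(p.cl, p.v, p.v2, p.q, reg)
    return troughs


def find_regimen(
    model: PopulationModel,
    posterior: PosteriorEstimate,
    target: TargetSpec,
    constraints: SearchConstraints = SearchConstraints(),
) -> Regimen:
    """Regimen on the search grid whose predicted metric best centers the band.

    Exhaustive search over intervals x rounded doses; only regimens whose
    predicted metric lies inside [lower, upper] are feasible.  Among
    feasible regimens the one closest to the band midpoint wins; ties break
    toward the longer interval, then the smaller dose.  Raises
    NoFeasibleRegimenError when the grid contains no in-band regimen.
    """
    inc = constraints.dose_increment_mg
    lo = constraints.min_dose_mg if constraints.min_dose_mg is not None else inc
    n_steps = int(np.floor(constraints.max_dose_mg / inc))
    doses = np.arange(1, n_steps + 1) * inc
    doses = doses[doses >= lo - 1e-9]
    candidates = []  # (distance, -interval, dose, regimen)
    for interval in constraints.intervals_h:
        dur = min(constraints.infusion_duration_h, interval)
        metric = _predicted_metric(posterior, doses, interval, target, dur)
        inband = (metric >= target.lower) & (metric <= target.upper)
        for d, m in zip(doses[inband], metric[inband]):
            candidates.append(
                (abs(m - target.midpoint), -interval, d,
                 Regimen(float(d), float(interval), dur))
            )
    if not candidates:
        raise NoFeasibleRegimenError(
            f"no feasible regimen: no interval in {constraints.intervals_h} "
            f"with doses up to {constraints.max_dose_mg:g} mg attains "
            f"{target.metric} in [{target.lower:g}, {target.upper:g}]"
        )
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    return candidates[0][3]


@dataclass(frozen=True)
class StartingDose:
    """Empiric starting regimen plus any advisory flags."""

    regimen: Regimen
    basis: str  # "guideline_weight_based" or "model_based"
    flags: tuple[str, ...] = ()


def _round_dose(dose_mg: float, increment: float) -> float:
    # half-up, so a dose exactly between grid points rounds to the larger one
    return max(increment, math.floor(dose_mg / increment + 0.5) * increment)


def empiric_starting_dose(
    covariates: CovariateRecord,
    model_id: str,
    config: RunConfig = DEFAULT_CONFIG,
    target: TargetSpec | None = None,
) -> StartingDose:
    """Guideline empiric start.

    Children: 15 mg/kg per dose, q6h under 12 years and q8h at or above,
    extended to q12h with a renal flag when eGFR < 75 ml/min/1.73 m^2; if
    height is missing the eGFR cannot be computed and the dose carries a
    "renal function unverified" warning.  Neonates: model-based start — the
    dose grid is searched against the configured exposure target using the
    neonatal prior (no TDM yet).
    """
    target = target or config.target
    if model_id == "frymoyer_neonatal":
        from .estimate import fit_map
        from .course import PatientCourse

        course = PatientCourse(
            patient_id="empiric",
            model_id=model_id,
            covariates=[covariates],
            doses=[],
        )
        posterior = fit_map(get_model(model_id), course, config)
        constraints = SearchConstraints(
            intervals_h=config.intervals_h,
            dose_increment_mg=config.rounding_increment(
                covariates.weight_kg, neonate=True
            ),
            max_dose_mg=min(config.max_dose_mg, 60.0 * covariates.weight_kg),
            infusion_duration_h=config.default_infusion_duration_h,
        )
        regimen = find_regimen(get_model(model_id), posterior, target,
                               constraints)
        return StartingDose(regimen=regimen, basis="model_based")

    # pediatric tier: weight-based guideline dose
    inc = config.rounding_increment(covariates.weight_kg, neonate=False)
    dose = _round_dose(15.0 * covariates.weight_kg, inc)
    interval = 6.0 if covariates.chronological_age_days < 12 * 365.25 else 8.0
    flags: list[str] = []
    try:
        egfr = schwartz_egfr(
            covariates.height_cm if covariates.height_cm is not None else -1.0,
            max(covariates.serum_creatinine_mg_dl, config.creatinine_floor),
        )
    except ValidationError:
        egfr = None
        flags.append("renal function unverified: eGFR unavailable (height missing)")
    if egfr is not None and egfr < EGFR_REDUCED_RENAL:
        interval = 12.0
        flags.append(
            f"reduced renal function (eGFR {egfr:.0f} < {EGFR_REDUCED_RENAL:.0f} "
            "ml/min/1.73 m^2): interval extended; clinician review advised"
        )
    regimen = Regimen(dose, interval, config.default_infusion_duration_h)
    return StartingDose(regimen=regimen, basis="guideline_weight_based",
                        flags=tuple(flags))


def tdm_advice(
    covariate_timeline: list[CovariateRecord],
    config: RunConfig = DEFAULT_CONFIG,
) -> str:
    """Advisory message on when to draw the first TDM level.

    Default: trough before the fourth dose.  Renal function counted as
    impaired or unstable (draw sooner) when the latest eGFR is under 75
    ml/min/1.73 m^2 or creatinine rose by more than 0.3 mg/dL between
    consecutive measurements.
    """
    latest = covariate_timeline[-1]
    unstable = False
    creatinines = [c.serum_creatinine_mg_dl for c in covariate_timeline]
    if any(b - a > 0.3 for a, b in zip(creatinines, creatinines[1:])):
        unstable = True
    if latest.height_cm is not None:
        egfr = schwartz_egfr(
            latest.height_cm,
            max(latest.serum_creatinine_mg_dl, config.creatinine_floor),
        )
        if egfr < EGFR_REDUCED_RENAL:
            unstable = True
    if unstable:
        return (
            "Impaired or unstable renal function: draw a trough concentration "
            "earlier than the fourth dose."
        )
    return "Draw a trough concentration before the fourth dose."
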