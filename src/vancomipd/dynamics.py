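"""Closed-form concentration-time prediction for intermittent infusions.

Both supported structural models are linear, so every dose's contribution is
a sum of exponentials and a dose history superposes.  A unit IV bolus gives

    C(t) = sum_i  c_i * exp(-lambda_i * t)

with one term for the one-compartment model (lambda = CL/V, c = 1/V) and two
terms for the two-compartment model, whose macro-constants come from the
micro-constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 via the standard
quadratic eigen-decomposition:

    alpha + beta = k10 + k12 + k21,     alpha * beta = k10 * k21
    c_alpha = (alpha - k21) / (V1 * (alpha - beta))
    c_beta  = (k21 - beta)  / (V1 * (alpha - beta))

A zero-order infusion of rate R0 over duration T then has, per exponential
term, the textbook piecewise solution used throughout this module.  All
quantitative outputs (troughs, AUCs) use these closed forms; plotting grids
never enter any computation.

The helpers accept NumPy arrays for the PK parameters so that Monte-Carlo
parameter draws evaluate in a single vectorized pass.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .models import IndividualParameters, TypicalParameters


@dataclass(frozen=True)
class DoseEvent:
    """One administered dose."""

    start_time_h: float
    amount_mg: float
    infusion_duration_h: float = 1.0

    def __post_init__(self):
        if self.amount_mg <= 0:
            raise ValidationError("dose amount must be positive")
        if self.infusion_duration_h <= 0:
            raise ValidationError("infusion duration must be positive")


@dataclass(frozen=True)
class Regimen:
    """A repeating dosing regimen: dose every tau hours, infused over T hours."""

    dose_mg: float
    interval_h: float
    infusion_duration_h: float = 1.0

    def __post_init__(self):
        if self.dose_mg <= 0:
            raise ValidationError("dose must be positive")
        if self.interval_h <= 0:
            raise ValidationError("interval must be positive")
        if not 0 < self.infusion_duration_h <= self.interval_h:
            raise ValidationError(
                "infusion duration must be in (0, interval]"
            )

    @property
    def daily_dose_mg(self) -> float:
        return self.dose_mg * 24.0 / self.interval_h

    def doses(self, n: int, start_h: float = 0.0) -> list[DoseEvent]:
        """Expand to n consecutive dose events."""
        return [
            DoseEvent(start_h + i * self.interval_h, self.dose_mg,
                      self.infusion_duration_h)
            for i in range(n)
        ]


@dataclass(frozen=True)
class ConcentrationProfile:
    times_h: np.ndarray
    concentrations_mg_l: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.times_h, "conc_mg_per_L": self.concentrations_mg_l}
        )


@dataclass(frozen=True)
class ExposureSummary:
    """Steady-state exposure metrics for a regimen (and optional attainment)."""

    auc24_ss: float          # mg*h/L
    trough_ss: float         # mg/L
    p_auc24_gt_400: float | None = None
    p_trough_gt_20: float | None = None
    auc_cumulative: float | None = None

    def to_dict(self) -> dict:
        return {
            "auc24_ss_mg_h_per_L": self.auc24_ss,
            "trough_ss_mg_per_L": self.trough_ss,
            "p_auc24_gt_400": self.p_auc24_gt_400,
            "p_trough_gt_20": self.p_trough_gt_20,
            "auc_cumulative_mg_h_per_L": self.auc_cumulative,
        }


def _as_typical(params) -> TypicalParameters:
    if isinstance(params, IndividualParameters):
        return params.realized
    return params


def disposition_terms(cl, v, v2=None, q=None):
    """Exponential rates and bolus coefficients, vectorized over parameters.

    Returns (lambdas, coefs) with a trailing axis over exponential terms.
    Concentration after a unit (1 mg) bolus is sum(coefs * exp(-lambdas*t)).
    """
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    if v2 is None:
        lam = (cl / v)[..., None]
        coef = (1.0 / v)[..., None]
        return lam, coef
    v2 = np.asarray(v2, dtype=float)
    q = np.asarray(q, dtype=float)
    k10 = cl / v
    k12 = q / v
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    denom = v * (alpha - beta)
    c_a = (alpha - k21) / denom
    c_b = (k21 - beta) / denom
    lam = np.stack([alpha, beta], axis=-1)
    coef = np.stack([c_a, c_b], axis=-1)
    return lam, coef


def _terms_for(params):
    p = _as_typical(params)
    return disposition_terms(p.cl, p.v, p.v2, p.q)


def _infusion_conc(lam, coef, rate, t_rel, duration):
    """Concentration of one infusion at relative times t_rel (vectorized).

    lam/coef have a trailing term axis; t_rel broadcasts against the leading
    axes.  Zero before the infusion starts.
    """
    t = np.asarray(t_rel, dtype=float)[..., None]
    during = (rate / lam) * coef * -np.expm1(-lam * np.minimum(t, duration))
    decay = np.exp(-lam * np.maximum(t - duration, 0.0))
    out = (during * decay).sum(axis=-1)
    return np.where(np.asarray(t_rel) < 0.0, 0.0, out)


def predict_concentration(params, doses, times) -> ConcentrationProfile:
    """Superposed concentration profile of an arbitrary dose history.

    Times before the first dose (or negative) return 0.  Overlapping
    infusions superpose.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    lam, coef = _terms_for(params)
    conc = np.zeros_like(times)
    for d in sorted(doses, key=lambda d: d.start_time_h):
        rate = d.amount_mg / d.infusion_duration_h
        conc = conc + _infusion_conc(
            lam, coef, rate, times - d.start_time_h, d.infusion_duration_h
        )
    return ConcentrationProfile(times, conc)


def _infusion_auc(lam, coef, rate, t_rel, duration):
    """Exact integral of one infusion's concentration from 0 to t_rel."""
    t = np.asarray(t_rel, dtype=float)[..., None]
    u = np.minimum(np.maximum(t, 0.0), duration)      # time within infusion
    w = np.maximum(t - duration, 0.0)                  # time past infusion end
    a = coef * rate / lam
    during = a * (u + np.expm1(-lam * u) / lam)
    post = a * (-np.expm1(-lam * duration)) * (-np.expm1(-lam * w)) / lam
    return (during + post).sum(axis=-1)


def cumulative_auc(params, doses, t_end: float) -> float:
    """Exact AUC (mg*h/L) of the superposed profile from 0 to t_end."""
    if t_end < 0:
        raise ValidationError("t_end must be nonnegative")
    lam, coef = _terms_for(params)
    total = 0.0
    for d in doses:
        rate = d.amount_mg / d.infusion_duration_h
        total += float(
            _infusion_auc(lam, coef, rate, t_end - d.start_time_h,
                          d.infusion_duration_h)
        )
    return total


def steady_state_auc24(cl, regimen: Regimen):
    """Steady-state AUC over 24 h: (24/tau) * dose / CL (exact for linear PK)."""
    cl = np.asarray(cl, dtype=float)
    return (24.0 / regimen.interval_h) * regimen.dose_mg / cl


def steady_state_trough(cl, v, v2=None, q=None, regimen: Regimen = None):
    """Steady-state concentration at t = tau after a dose start (pre-dose).

    Closed form from the geometric superposition of the infinite dose train:
    each exponential term accumulates by a factor 1/(1 - exp(-lambda*tau)).
    """
    lam, coef = disposition_terms(cl, v, v2, q)
    tau = regimen.interval_h
    dur = regimen.infusion_duration_h
    rate = regimen.dose_mg / dur
    single = (rate / lam) * coef * -np.expm1(-lam * dur) * np.exp(
        -lam * (tau - dur)
    )
    accum = single / -np.expm1(-lam * tau)
    return accum.sum(axis=-1)


def steady_state_metrics(params, regimen: Regimen) -> ExposureSummary:
    """Point (no-uncertainty) steady-state AUC24 and trough for a regimen."""
    p = _as_typical(params)
    auc = float(steady_state_auc24(p.cl, regimen))
    trough = float(steady_state_trough(p.cl, p.v, p.v2, p.q, regimen))
    return ExposureSummary(auc24_ss=auc, trough_ss=trough)


def profile_grid(params, doses, t_end: float, resolution_h: float = 0.1
                 ) -> ConcentrationProfile:
    """Evenly sampled profile for display/export (not used for metrics)."""
    times = np.arange(0.0, t_end + 0.5 * resolution_h, resolution_h)
    return predict_concentration(params, doses, times)
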