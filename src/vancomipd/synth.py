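"""Synthetic neonatal/pediatric cohorts and closed-loop TDM simulation.

The generator emulates the covariate mix of a children's-hospital vancomycin
population: log-normal covariate distributions matched to published
median/IQR summaries, true individual PK sampled from the population
model's log-normal interindividual variability, protocolized dosing from
the empiric starting-dose rules, and trough TDM drawn before the fourth
dose with the model's combined proportional+additive residual error.

Everything is driven by one integer seed and is fully reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .advisor import empiric_starting_dose, find_regimen
from .config import DEFAULT_CONFIG, RunConfig, TargetSpec
from .course import PatientCourse, TdmObservation, predict_course
from .dynamics import DoseEvent, Regimen, steady_state_auc24, steady_state_trough
from .errors import NoFeasibleRegimenError, ValidationError
from .estimate import fit_map
from .models import CovariateRecord, get_model, select_model

#: a gap of more than this between doses starts a new treatment course
COURSE_GAP_DAYS = 14.0

_Z_IQR = 0.6744897501960817  # standard normal quantile at 0.75


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution pinned to a median and interquartile range."""

    median: float
    q1: float
    q3: float
    lo: float | None = None  # truncation bounds (resampled)
    hi: float | None = None

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        mu = np.log(self.median)
        sigma = (np.log(self.q3) - np.log(self.q1)) / (2.0 * _Z_IQR)
        x = rng.lognormal(mu, sigma, size=n)
        if self.lo is not None or self.hi is not None:
            lo = self.lo if self.lo is not None else -np.inf
            hi = self.hi if self.hi is not None else np.inf
            for _ in range(1000):
                bad = (x < lo) | (x > hi)
                if not bad.any():
                    break
                x[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
            x = np.clip(x, lo, hi)
        return x


#: Covariate distributions emulating the neonatal platform population
NEONATAL_COVARIATES = {
    "age_days": LogNormalSpec(44.0, 21.0, 76.0, lo=1.5, hi=200.0),
    "weight_kg": LogNormalSpec(3.1, 2.2, 3.9, lo=0.5, hi=8.0),
    "height_cm": LogNormalSpec(49.0, 42.4, 54.0, lo=30.0, hi=70.0),
    "creatinine": LogNormalSpec(0.3, 0.2, 0.6, lo=0.1, hi=2.5),
    # gestational age is left-skewed: sampled as 42 - lognormal
    "ga_deficit_weeks": LogNormalSpec(42.0 - 39.3, 42.0 - 40.0, 42.0 - 35.4,
                                      lo=0.0, hi=20.0),
    "duration_days": LogNormalSpec(7.0, 2.0, 12.0, lo=1.0, hi=30.0),
}

#: Covariate distributions emulating the child platform population
PEDIATRIC_COVARIATES = {
    "age_years": LogNormalSpec(6.0, 1.7, 13.4, lo=0.26, hi=18.0),
    "weight_kg": LogNormalSpec(19.1, 9.7, 42.6, lo=3.0, hi=120.0),
    "height_cm": LogNormalSpec(105.0, 73.0, 148.0, lo=45.0, hi=200.0),
    "creatinine": LogNormalSpec(0.4, 0.2, 0.6, lo=0.1, hi=3.0),
    "duration_days": LogNormalSpec(6.0, 2.0, 13.0, lo=1.0, hi=30.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """What to generate."""

    n_patients: int
    population: str = "neonatal"  # or "pediatric"
    residual_noise: bool = True
    seed: int = 0
    tdm_before_dose: int = 4
    covariates: dict = field(default_factory=dict)  # overrides of the tables

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.population not in ("neonatal", "pediatric"):
            raise ValidationError("population must be 'neonatal' or 'pediatric'")


def _dist(spec: CohortSpec, name: str) -> LogNormalSpec:
    base = NEONATAL_COVARIATES if spec.population == "neonatal" else PEDIATRIC_COVARIATES
    return spec.covariates.get(name, base[name])


def _sample_covariates(spec: CohortSpec, rng: np.random.Generator
                       ) -> CovariateRecord:
    if spec.population == "neonatal":
        # resample until the patient lands in the <52-week PMA tier
        for _ in range(1000):
            ga = 42.0 - float(_dist(spec, "ga_deficit_weeks").sample(rng)[0])
            age_d = float(_dist(spec, "age_days").sample(rng)[0])
            pma = ga + age_d / 7.0
            if 24.0 <= pma < 52.0:
                break
        return CovariateRecord(
            weight_kg=float(_dist(spec, "weight_kg").sample(rng)[0]),
            serum_creatinine_mg_dl=float(_dist(spec, "creatinine").sample(rng)[0]),
            chronological_age_days=age_d,
            gestational_age_weeks=ga,
            postmenstrual_age_weeks=pma,
            height_cm=float(_dist(spec, "height_cm").sample(rng)[0]),
            sex="F" if rng.random() < 0.35 else "M",
        )
    age_y = float(_dist(spec, "age_years").sample(rng)[0])
    return CovariateRecord(
        weight_kg=float(_dist(spec, "weight_kg").sample(rng)[0]),
        serum_creatinine_mg_dl=float(_dist(spec, "creatinine").sample(rng)[0]),
        chronological_age_days=age_y * 365.25,
        height_cm=float(_dist(spec, "height_cm").sample(rng)[0]),
        sex="F" if rng.random() < 0.44 else "M",
    )


def _observe(course: PatientCourse, time_h: float, eta, noisy: bool,
             rng: np.random.Generator, config: RunConfig) -> TdmObservation:
    """Draw a TDM level: true individual concentration plus residual error."""
    f = float(predict_course(course, eta, [time_h], config)[0])
    if noisy:
        model = course.model
        prop = model.residual_proportional_cv / 100.0
        y = f * (1.0 + prop * rng.standard_normal()) \
            + model.residual_additive_sd * rng.standard_normal()
        y = max(y, 0.01)  # assay floor; keeps concentrations positive
    else:
        y = max(f, 0.01)
    return TdmObservation(time_h=time_h, concentration_mg_l=y)


def generate_cohort(spec: CohortSpec, config: RunConfig = DEFAULT_CONFIG
                    ) -> list[PatientCourse]:
    """Virtual patients with true PK, protocolized doses and one trough TDM."""
    rng = np.random.default_rng(spec.seed)
    cohort = []
    for i in range(spec.n_patients):
        cov = _sample_covariates(spec, rng)
        model_id = select_model(
            chronological_age_days=cov.chronological_age_days,
            gestational_age_weeks=cov.gestational_age_weeks,
            postmenstrual_age_weeks=cov.postmenstrual_age_weeks,
            config=config,
        )
        model = get_model(model_id)
        omega = model.omegas(config)
        eta = rng.normal(0.0, omega)
        start = empiric_starting_dose(cov, model_id, config)
        regimen = start.regimen
        duration_h = float(_dist(spec, "duration_days").sample(rng)[0]) * 24.0
        n_doses = max(int(np.ceil(duration_h / regimen.interval_h)),
                      spec.tdm_before_dose)
        course = PatientCourse(
            patient_id=f"{spec.population[:4]}-{i + 1:04d}",
            model_id=model_id,
            covariates=[cov],
            doses=regimen.doses(n_doses),
            true_eta=tuple(eta),
        )
        tdm_time = (spec.tdm_before_dose - 1) * regimen.interval_h
        obs = _observe(course, tdm_time, eta, spec.residual_noise, rng, config)
        course.observations = [obs]
        cohort.append(course)
    return cohort


def split_courses(doses: list[DoseEvent],
                  gap_days: float = COURSE_GAP_DAYS) -> list[list[DoseEvent]]:
    """Split a dose history into treatment courses.

    A new course starts whenever the gap since the previous dose strictly
    exceeds gap_days (default 14 days); a gap of exactly 14 days does not
    split.
    """
    if not doses:
        return []
    doses = sorted(doses, key=lambda d: d.start_time_h)
    gap_h = gap_days * 24.0
    courses = [[doses[0]]]
    for prev, cur in zip(doses, doses[1:]):
        if cur.start_time_h - prev.start_time_h > gap_h:
            courses.append([cur])
        else:
            courses[-1].append(cur)
    return courses


@dataclass(frozen=True)
class RoundSummary:
    """Predicted steady-state exposure at one TDM round, across the cohort."""

    tdm_index: int
    median_auc24: float
    auc24_iqr: tuple[float, float]
    median_trough: float
    trough_iqr: tuple[float, float]
    cum_pct_auc_over_mic_gt_400: float
    cum_pct_trough_5_20: float
    cum_pct_trough_10_20: float


@dataclass(frozen=True)
class AttainmentReport:
    rounds: tuple[RoundSummary, ...]
    n_patients: int
    mic: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "tdm_index": r.tdm_index,
                    "auc24_ss_median": r.median_auc24,
                    "auc24_ss_q1": r.auc24_iqr[0],
                    "auc24_ss_q3": r.auc24_iqr[1],
                    "trough_ss_median": r.median_trough,
                    "trough_ss_q1": r.trough_iqr[0],
                    "trough_ss_q3": r.trough_iqr[1],
                    "cum_pct_auc_over_mic_gt_400": r.cum_pct_auc_over_mic_gt_400,
                    "cum_pct_trough_5_20": r.cum_pct_trough_5_20,
                    "cum_pct_trough_10_20": r.cum_pct_trough_10_20,
                }
                for r in self.rounds
            ]
        )


def attainment_report(
    cohort: list[PatientCourse],
    rounds: int = 3,
    target: TargetSpec | None = None,
    mic: float = 1.0,
    config: RunConfig = DEFAULT_CONFIG,
    residual_noise: bool = True,
    seed: int = 0,
) -> AttainmentReport:
    """Closed-loop MIPD simulation with per-round attainment.

    Each round administers three doses of the round's regimen, draws a
    trough before the fourth scheduled dose, refits the MAP posterior on all
    observations so far, records the predicted steady-state exposure of the
    regimen in effect, and adjusts the regimen (effective at the next
    scheduled dose) by searching the target band.  Cumulative attainment at
    round r is the percentage of patients whose predicted exposure hit the
    criterion at any round <= r.
    """
    target = target or config.target
    rng = np.random.default_rng(seed)
    n = len(cohort)
    auc = np.empty((rounds, n))
    trough = np.empty((rounds, n))
    for j, course in enumerate(cohort):
        if course.true_eta is None:
            raise ValidationError(
                "attainment_report needs synthetic courses with true_eta"
            )
        model = course.model
        eta = np.asarray(course.true_eta)
        if len(course.doses) < 2:
            raise ValidationError("course must carry a starting regimen")
        d0, d1 = course.doses[0], course.doses[1]
        regimen = Regimen(d0.amount_mg, d1.start_time_h - d0.start_time_h,
                          d0.infusion_duration_h)
        doses: list[DoseEvent] = []
        observations: list[TdmObservation] = []
        t = 0.0
        for r in range(rounds):
            doses.extend(regimen.doses(3, start_h=t))
            t += 3 * regimen.interval_h
            sim = replace(course, doses=doses, observations=[])
            observations.append(
                _observe(sim, t, eta, residual_noise, rng, config)
            )
            fitted = replace(course, doses=doses, observations=observations)
            posterior = fit_map(model, fitted, config)
            p = posterior.realized()
            auc[r, j] = float(steady_state_auc24(p.cl, regimen))
            trough[r, j] = float(
                steady_state_trough(p.cl, p.v, p.v2, p.q, regimen)
            )
            try:
                regimen = find_regimen(model, posterior, target,
                                       _constraints_for(course, config))
            except NoFeasibleRegimenError:
                pass  # keep the current regimen
    hit_auc = (auc / mic) > 400.0
    hit_5_20 = (trough >= 5.0) & (trough <= 20.0)
    hit_10_20 = (trough >= 10.0) & (trough <= 20.0)
    out = []
    for r in range(rounds):
        cum = slice(0, r + 1)
        out.append(
            RoundSummary(
                tdm_index=r + 1,
                median_auc24=float(np.median(auc[r])),
                auc24_iqr=tuple(np.percentile(auc[r], [25, 75])),
                median_trough=float(np.median(trough[r])),
                trough_iqr=tuple(np.percentile(trough[r], [25, 75])),
                cum_pct_auc_over_mic_gt_400=float(
                    100.0 * hit_auc[cum].any(axis=0).mean()
                ),
                cum_pct_trough_5_20=float(
                    100.0 * hit_5_20[cum].any(axis=0).mean()
                ),
                cum_pct_trough_10_20=float(
                    100.0 * hit_10_20[cum].any(axis=0).mean()
                ),
            )
        )
    return AttainmentReport(rounds=tuple(out), n_patients=n, mic=mic)


def _constraints_for(course: PatientCourse, config: RunConfig):
    from .advisor import SearchConstraints

    cov = course.covariates[0]
    neonate = course.model_id == "frymoyer_neonatal"
    return SearchConstraints(
        intervals_h=config.intervals_h,
        dose_increment_mg=config.rounding_increment(cov.weight_kg, neonate),
        max_dose_mg=min(config.max_dose_mg, 100.0 * cov.weight_kg),
        infusion_duration_h=config.default_infusion_duration_h,
    )
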