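"""Population pharmacokinetic models of vancomycin and age-based selection.

Three published models drive the engine:

* ``frymoyer_neonatal`` — one-compartment neonatal model; clearance scales
  allometrically with weight, inversely with serum creatinine, and follows a
  sigmoidal maturation function of postmenstrual age (half-maximal at
  34.8 weeks).
* ``le_pediatric`` — one-compartment pediatric model; clearance scales
  allometrically with weight, inversely with creatinine, and with the
  logarithm of age in days.
* ``thomson`` — two-compartment adult/adolescent model; clearance is linear
  in creatinine clearance around 66 ml/min, volumes scale per kg.

Model selection is by maturational age: patients under 52 weeks
postmenstrual age use the neonatal model; patients at or above 52 weeks (or,
when gestational age is unknown, at or above 3 months chronological age) use
a pediatric-tier model.

Constants live in the ``models.yaml`` catalog shipped with the package so a
parameter revision does not require a code change.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .config import DEFAULT_CONFIG, RunConfig
from .errors import MissingCovariateError, ModelUndeterminedError, ValidationError

NEONATAL_MODEL = "frymoyer_neonatal"
PEDIATRIC_MODELS = ("le_pediatric", "thomson")
PMA_CUTOFF_WEEKS = 52.0
AGE_CUTOFF_DAYS = 3 * 30.4375  # 3 months


@dataclass(frozen=True)
class CovariateRecord:
    """A snapshot of the covariates a PK model may require.

    Times are hours from the start of the treatment course; ages are at the
    start of the course.  ``crcl_ml_min`` may be supplied directly; otherwise
    it is derived from height and creatinine via the Schwartz equation when
    the two-compartment model needs it.
    """

    weight_kg: float
    serum_creatinine_mg_dl: float
    chronological_age_days: float
    postmenstrual_age_weeks: float | None = None
    gestational_age_weeks: float | None = None
    height_cm: float | None = None
    sex: str | None = None
    crcl_ml_min: float | None = None
    effective_time_h: float = 0.0

    def __post_init__(self):
        if self.weight_kg <= 0:
            raise ValidationError("weight must be positive")
        if self.serum_creatinine_mg_dl <= 0:
            raise ValidationError("serum creatinine must be positive")
        if self.chronological_age_days < 0:
            raise ValidationError("chronological age must be nonnegative")
        if self.height_cm is not None and self.height_cm <= 0:
            raise ValidationError("height must be positive")
        if (
            self.postmenstrual_age_weeks is not None
            and self.gestational_age_weeks is not None
        ):
            implied = self.gestational_age_weeks + self.chronological_age_days / 7.0
            if abs(implied - self.postmenstrual_age_weeks) > 1.0:
                raise ValidationError(
                    "postmenstrual age inconsistent with gestational age + "
                    f"postnatal age ({self.postmenstrual_age_weeks:.1f} vs "
                    f"{implied:.1f} weeks)"
                )

    @property
    def pma_weeks(self) -> float | None:
        """Postmenstrual age, derived from GA + postnatal age if not given."""
        if self.postmenstrual_age_weeks is not None:
            return self.postmenstrual_age_weeks
        if self.gestational_age_weeks is not None:
            return self.gestational_age_weeks + self.chronological_age_days / 7.0
        return None


@dataclass(frozen=True)
class TypicalParameters:
    """Typical-value PK parameters; V2/Q are None for one-compartment models."""

    cl: float  # L/h
    v: float   # L (central volume; V1 for two-compartment)
    v2: float | None = None  # L
    q: float | None = None   # L/h

    def __post_init__(self):
        for name, val in (("CL", self.cl), ("V", self.v)):
            if not (math.isfinite(val) and val > 0):
                raise ValidationError(f"{name} must be finite and positive")
        if (self.v2 is None) != (self.q is None):
            raise ValidationError("V2 and Q must be given together")
        if self.v2 is not None:
            if not (math.isfinite(self.v2) and self.v2 > 0):
                raise ValidationError("V2 must be finite and positive")
            if not (math.isfinite(self.q) and self.q > 0):
                raise ValidationError("Q must be finite and positive")

    @property
    def n_compartments(self) -> int:
        return 1 if self.v2 is None else 2


@dataclass(frozen=True)
class IndividualParameters:
    """Realized individual parameters: typical values scaled by exp(eta)."""

    typical: TypicalParameters
    eta: tuple[float, ...]
    realized: TypicalParameters


@dataclass(frozen=True)
class PopulationModel:
    """One entry of the model catalog."""

    model_id: str
    n_compartments: int
    structure: dict
    iiv_cv: dict
    residual_proportional_cv: float
    residual_additive_sd: float

    #: order of the log-normal random effects (eta vector layout)
    @property
    def eta_names(self) -> tuple[str, ...]:
        return tuple(self.iiv_cv.keys())

    def omegas(self, config: RunConfig = DEFAULT_CONFIG) -> np.ndarray:
        """Log-normal SDs of the random effects, per the CV->omega convention."""
        cv = np.array([self.iiv_cv[n] for n in self.eta_names]) / 100.0
        if config.cv_to_omega == "exact":
            return np.sqrt(np.log1p(cv**2))
        return cv

    def residual_sd(self, f):
        """SD of the combined proportional+additive residual at prediction f."""
        f = np.asarray(f, dtype=float)
        prop = self.residual_proportional_cv / 100.0
        return np.sqrt((prop * f) ** 2 + self.residual_additive_sd**2)


def _load_catalog() -> dict[str, PopulationModel]:
    raw = yaml.safe_load(
        resources.files("vancomipd").joinpath("models.yaml").read_text()
    )
    catalog = {}
    for model_id, entry in raw["models"].items():
        catalog[model_id] = PopulationModel(
            model_id=model_id,
            n_compartments=int(entry["n_compartments"]),
            structure=dict(entry["structure"]),
            iiv_cv=dict(entry["iiv_cv"]),
            residual_proportional_cv=float(entry["residual_proportional_cv"]),
            residual_additive_sd=float(entry["residual_additive_sd"]),
        )
    return catalog


_CATALOG = _load_catalog()


def get_model(model_id: str) -> PopulationModel:
    try:
        return _CATALOG[model_id]
    except KeyError:
        raise ValidationError(
            f"unknown model {model_id!r}; available: {sorted(_CATALOG)}"
        ) from None


def available_models() -> tuple[str, ...]:
    return tuple(_CATALOG)


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2), Mosteller formula."""
    return math.sqrt(height_cm * weight_kg / 3600.0)


def _creatinine(cov: CovariateRecord, config: RunConfig) -> float:
    return max(cov.serum_creatinine_mg_dl, config.creatinine_floor)


def _thomson_crcl(cov: CovariateRecord, config: RunConfig) -> float:
    if cov.crcl_ml_min is not None:
        return cov.crcl_ml_min
    if cov.height_cm is None:
        raise MissingCovariateError("height (for CrCl via Schwartz eGFR)", "thomson")
    # local import: dose_advisor owns the Schwartz equation
    from .advisor import schwartz_egfr

    egfr = schwartz_egfr(cov.height_cm, _creatinine(cov, config))
    if config.crcl_denormalize_bsa:
        return egfr * mosteller_bsa(cov.height_cm, cov.weight_kg) / 1.73
    return egfr


def frymoyer_maturation(pma_weeks: float, pma50: float = 34.8, hill: float = 4.53) -> float:
    """Sigmoidal maturation factor in (0, 1); 0.5 at pma50 exactly."""
    return 1.0 / (1.0 + (pma_weeks / pma50) ** (-hill))


def typical_parameters(
    model_id: str,
    covariates: CovariateRecord,
    config: RunConfig = DEFAULT_CONFIG,
) -> TypicalParameters:
    """Evaluate the selected model's covariate equations.

    Raises MissingCovariateError naming the covariate when a required field is
    absent, and ValidationError on nonpositive values.
    """
    model = get_model(model_id)
    s = model.structure
    wt = covariates.weight_kg
    cr = _creatinine(covariates, config)

    if model_id == "frymoyer_neonatal":
        pma = covariates.pma_weeks
        if pma is None:
            raise MissingCovariateError("postmenstrual age", model_id)
        if pma <= 0:
            raise ValidationError("postmenstrual age must be positive")
        cl = (
            s["cl_std"]
            * (wt / s["wt_ref"]) ** s["cl_wt_exp"]
            * (s["cr_ref"] / cr) ** s["cr_exp"]
            * frymoyer_maturation(pma, s["pma50"], s["hill"])
        )
        v = s["v_std"] * (wt / s["wt_ref"])
        return TypicalParameters(cl=cl, v=v)

    if model_id == "le_pediatric":
        age_d = covariates.chronological_age_days
        if age_d <= 1:
            # ln(age) must be positive for the power term to be meaningful
            raise ValidationError(
                "pediatric model requires chronological age > 1 day"
            )
        cl = (
            s["cl_std"]
            * wt ** s["cl_wt_exp"]
            * (s["cr_ref"] / cr) ** s["cr_exp"]
            * (math.log(age_d) / s["lnage_ref"]) ** s["age_exp"]
        )
        v = s["v_per_kg"] * wt
        return TypicalParameters(cl=cl, v=v)

    if model_id == "thomson":
        crcl = _thomson_crcl(covariates, config)
        if crcl <= 0:
            raise ValidationError("creatinine clearance must be positive")
        cl = s["cl_std"] * (1.0 + s["crcl_slope"] * (crcl - s["crcl_ref"]))
        if cl <= 0:
            raise ValidationError(
                f"CrCl {crcl:.1f} ml/min puts typical clearance at or below zero"
            )
        return TypicalParameters(
            cl=cl,
            v=s["v1_per_kg"] * wt,
            v2=s["v2_per_kg"] * wt,
            q=s["q"],
        )

    raise ValidationError(f"no covariate equations registered for {model_id!r}")


def select_model(
    chronological_age_days: float,
    gestational_age_weeks: float | None = None,
    postmenstrual_age_weeks: float | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> str:
    """Age-based model choice.

    PMA < 52 weeks -> neonatal model; PMA >= 52 weeks (GA known) or
    chronological age >= 3 months (GA unknown) -> pediatric tier, by default
    the one-compartment pediatric model (configurable).  GA unknown and age
    under 3 months cannot be resolved.
    """
    if config.model_override is not None:
        return config.model_override
    if chronological_age_days < 0:
        raise ValidationError("chronological age must be nonnegative")
    pma = postmenstrual_age_weeks
    if pma is None and gestational_age_weeks is not None:
        pma = gestational_age_weeks + chronological_age_days / 7.0
    if pma is not None:
        return NEONATAL_MODEL if pma < PMA_CUTOFF_WEEKS else config.pediatric_model
    if chronological_age_days >= AGE_CUTOFF_DAYS:
        return config.pediatric_model
    raise ModelUndeterminedError(
        "model undetermined: gestational age unknown and chronological age "
        f"{chronological_age_days:.0f} days is under 3 months"
    )


def realize_individual(
    model: PopulationModel | str,
    typical: TypicalParameters,
    eta,
) -> IndividualParameters:
    """Apply log-normal random effects: each variable parameter x exp(eta)."""
    if isinstance(model, str):
        model = get_model(model)
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    names = model.eta_names
    if eta.shape != (len(names),):
        raise ValidationError(
            f"eta must have length {len(names)} ({', '.join(names)}), "
            f"got shape {eta.shape}"
        )
    factors = dict(zip(names, np.exp(eta)))
    realized = TypicalParameters(
        cl=typical.cl * factors.get("CL", 1.0),
        v=typical.v * factors.get("V", factors.get("V1", 1.0)),
        v2=None if typical.v2 is None else typical.v2 * factors.get("V2", 1.0),
        q=None if typical.q is None else typical.q * factors.get("Q", 1.0),
    )
    return IndividualParameters(
        typical=typical, eta=tuple(float(e) for e in eta), realized=realized
    )
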