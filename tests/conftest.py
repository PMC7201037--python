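import numpy as np
import pytest

from vancomipd import CovariateRecord, Regimen, TdmObservation, get_model
from vancomipd.course import PatientCourse, predict_course


@pytest.fixture
def neonate_cov():
    """Reference neonate: the covariate point where all model ratios are 1."""
    return CovariateRecord(
        weight_kg=2.9,
        serum_creatinine_mg_dl=1.0,
        chronological_age_days=30.0,
        postmenstrual_age_weeks=34.8,
        height_cm=49.0,
    )


@pytest.fixture
def child_cov():
    return CovariateRecord(
        weight_kg=19.1,
        serum_creatinine_mg_dl=0.4,
        chronological_age_days=6 * 365.25,
        height_cm=105.0,
    )


@pytest.fixture
def neonatal_model():
    return get_model("frymoyer_neonatal")


def make_course(cov, model_id="frymoyer_neonatal", regimen=None, n_doses=8,
                obs=()):
    regimen = regimen or Regimen(45.0, 12.0, 1.0)
    return PatientCourse(
        patient_id="test",
        model_id=model_id,
        covariates=[cov],
        doses=regimen.doses(n_doses),
        observations=list(obs),
    )


def noise_free_observations(course, eta, times):
    conc = predict_course(course, np.asarray(eta), times)
    return [TdmObservation(float(t), float(c)) for t, c in zip(times, conc)]
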