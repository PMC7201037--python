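"""Bias/precision evaluation of model predictions against observed TDM levels.

Implements the Sheiner-Beal summary used to validate population models
against an external cohort: prediction error PE_j = predicted_j - observed_j
(mg/L), summarized by the median PE (bias) and median |PE| (precision), each
with a distribution-free 95% confidence interval from binomial order
statistics, plus the percentage of predictions within 25% of the observed
concentration (|PE|/observed <= 0.25, boundary inclusive).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class PredictionErrors:
    pe: np.ndarray                 # predicted - observed, mg/L
    ape: np.ndarray                # |pe|
    within_25: np.ndarray          # bool, |pe|/observed <= 0.25


@dataclass(frozen=True)
class EvaluationStats:
    median_pe: float
    median_pe_ci: tuple[float, float]
    median_ape: float
    median_ape_ci: tuple[float, float]
    pct_within_25: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "median_pe_mg_per_L": self.median_pe,
            "median_pe_95ci": list(self.median_pe_ci),
            "median_ape_mg_per_L": self.median_ape,
            "median_ape_95ci": list(self.median_ape_ci),
            "pct_within_25": self.pct_within_25,
            "n_pairs": self.n_pairs,
        }


def prediction_errors(predicted, observed) -> PredictionErrors:
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValidationError(
            f"length mismatch: {predicted.shape} predicted vs "
            f"{observed.shape} observed"
        )
    if np.any(observed <= 0) or np.any(predicted <= 0):
        raise ValidationError("concentrations must be positive")
    pe = predicted - observed
    return PredictionErrors(pe=pe, ape=np.abs(pe),
                            within_25=np.abs(pe) / observed <= 0.25)


def _median_ci(values: np.ndarray, level: float) -> tuple[float, float]:
    """Distribution-free CI for the median from binomial order statistics.

    The interval [x_(l), x_(u)] with l = largest k such that
    P(Binom(n, 1/2) < k) <= alpha/2 (1-based ranks) has coverage >= level.
    """
    n = len(values)
    x = np.sort(values)
    alpha = 1.0 - level
    l = int(stats.binom.ppf(alpha / 2, n, 0.5))  # 0-based lower index
    if stats.binom.cdf(l, n, 0.5) > alpha / 2:
        l -= 1
    l = max(l, 0)
    u = n - 1 - l
    return float(x[l]), float(x[u])


def summarize(errors: PredictionErrors, ci_level: float = 0.95
              ) -> EvaluationStats:
    """Sheiner-Beal medians with order-statistic CIs and % within 25%."""
    n = len(errors.pe)
    if n < 1:
        raise ValidationError("need at least one prediction-observation pair")
    if n < 6:
        warnings.warn(
            f"n={n} pairs is too few for a {ci_level:.0%} order-statistic CI; "
            "reporting the full data range",
            stacklevel=2,
        )
        pe_ci = (float(errors.pe.min()), float(errors.pe.max()))
        ape_ci = (float(errors.ape.min()), float(errors.ape.max()))
    else:
        pe_ci = _median_ci(errors.pe, ci_level)
        ape_ci = _median_ci(errors.ape, ci_level)
    return EvaluationStats(
        median_pe=float(np.median(errors.pe)),
        median_pe_ci=pe_ci,
        median_ape=float(np.median(errors.ape)),
        median_ape_ci=ape_ci,
        pct_within_25=float(100.0 * np.mean(errors.within_25)),
        n_pairs=n,
    )


def population_predictions(course, config=None) -> np.ndarray:
    """A-priori (eta = 0) predictions at the course's used TDM times."""
    from .config import DEFAULT_CONFIG
    from .course import predict_course

    config = config or DEFAULT_CONFIG
    times = [o.time_h for o in course.used_observations()]
    n_eta = len(course.model.eta_names)
    return predict_course(course, np.zeros(n_eta), times, config)


def individual_predictions(course, config=None) -> np.ndarray:
    """A-posteriori leave-latest-out predictions at the used TDM times.

    Each observation is predicted from a MAP fit to the observations that
    precede it (the first observation gets the population prediction), the
    evaluation mode that mimics prospective forecasting.
    """
    from dataclasses import replace as _replace

    from .config import DEFAULT_CONFIG
    from .course import predict_course
    from .estimate import fit_map

    config = config or DEFAULT_CONFIG
    obs = course.used_observations()
    preds = np.empty(len(obs))
    for j, o in enumerate(obs):
        sub = _replace(course, observations=list(obs[:j]))
        post = fit_map(course.model, sub, config)
        preds[j] = predict_course(course, post.eta_mode, [o.time_h], config)[0]
    return preds
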