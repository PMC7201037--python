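"""MAP (maximum a posteriori) estimation of individual PK parameters.

The population model supplies a log-normal prior on the random effects eta;
measured TDM concentrations update it.  The objective minimized is the
standard extended-least-squares form (proportional to -2 log posterior up to
a constant):

    OFV(eta) = sum_j [ (y_j - f_j(eta))^2 / g_j^2 + ln g_j^2 ]
             + sum_i eta_i^2 / omega_i^2

with residual variance g_j^2 = (prop * f_j)^2 + add^2 evaluated at the
individual prediction f_j.  The posterior is summarized by a Laplace
approximation at the mode: covariance = 2 * inverse Hessian of OFV (the
factor 2 converts the -2-log scale to the log scale).  With no observations
the posterior equals the prior exactly: eta = 0, covariance diag(omega^2).

Probability of target attainment propagates the remaining uncertainty by
Monte-Carlo sampling eta from the Laplace posterior and evaluating the
closed-form steady-state metrics per draw.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .config import DEFAULT_CONFIG, RunConfig
from .course import PatientCourse, predict_course, course_typical_parameters
from .dynamics import Regimen, steady_state_auc24, steady_state_trough
from .errors import ConvergenceError
from .models import PopulationModel, TypicalParameters, realize_individual

_HESS_STEP = 1e-4
_OBJ_TOL = 1e-8


@dataclass(frozen=True)
class PosteriorEstimate:
    """MAP mode, Laplace covariance, and the context needed to forecast."""

    model_id: str
    eta_mode: np.ndarray
    covariance: np.ndarray
    objective_value: float
    n_obs_used: int
    typical: TypicalParameters  # at the latest covariates of the fitted course

    @property
    def eta_names(self) -> tuple[str, ...]:
        from .models import get_model

        return get_model(self.model_id).eta_names

    def realized(self) -> TypicalParameters:
        return realize_individual(self.model_id, self.typical,
                                  self.eta_mode).realized

    def to_json(self, residuals=None) -> str:
        payload = {
            "model_id": self.model_id,
            "eta_names": list(self.eta_names),
            "eta_mode": self.eta_mode.tolist(),
            "covariance": self.covariance.tolist(),
            "objective_value": self.objective_value,
            "n_obs_used": self.n_obs_used,
        }
        if residuals is not None:
            payload["residuals"] = residuals
        return json.dumps(payload, indent=2)


def _usable_observations(course: PatientCourse):
    """Used observations at or after the first dose; warn on earlier ones."""
    if not course.doses:
        return []
    t0 = course.doses[0].start_time_h
    usable = []
    for o in course.used_observations():
        if o.time_h < t0:
            warnings.warn(
                f"TDM observation at t={o.time_h:.2f} h precedes the first "
                "dose and is excluded from the fit",
                stacklevel=3,
            )
        else:
            usable.append(o)
    return usable


def map_objective(
    eta,
    model: PopulationModel,
    course: PatientCourse,
    config: RunConfig = DEFAULT_CONFIG,
) -> float:
    """Extended-least-squares MAP objective at eta (see module docstring)."""
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    omega = model.omegas(config)
    value = float(np.sum(eta**2 / omega**2))
    obs = _usable_observations(course)
    if obs:
        times = np.array([o.time_h for o in obs])
        y = np.array([o.concentration_mg_l for o in obs])
        f = predict_course(course, eta, times, config)
        g2 = model.residual_sd(f) ** 2
        value += float(np.sum((y - f) ** 2 / g2 + np.log(g2)))
    return value


def _fd_hessian(fun, x, h=_HESS_STEP):
    """Central finite-difference Hessian."""
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h
        H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h**2)
    return H


def fit_map(
    model: PopulationModel,
    course: PatientCourse,
    config: RunConfig = DEFAULT_CONFIG,
) -> PosteriorEstimate:
    """MAP fit of the course's random effects.

    Derivative-free simplex start followed by BFGS refinement from eta = 0;
    deterministic for fixed inputs.  Raises ConvergenceError (with optimizer
    diagnostics attached) if neither stage converges.
    """
    omega = model.omegas(config)
    n = len(omega)
    typical = course_typical_parameters(course, config=config)
    obs = _usable_observations(course)
    if not obs:
        return PosteriorEstimate(
            model_id=model.model_id,
            eta_mode=np.zeros(n),
            covariance=np.diag(omega**2),
            objective_value=0.0,
            n_obs_used=0,
            typical=typical,
        )

    fun = lambda e: map_objective(e, model, course, config)
    x0 = np.zeros(n)
    nm = optimize.minimize(
        fun, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": _OBJ_TOL, "maxiter": 2000},
    )
    bfgs = optimize.minimize(
        fun, nm.x, method="BFGS", options={"gtol": 1e-9, "maxiter": 500}
    )
    best = bfgs if bfgs.fun <= nm.fun else nm
    if not (nm.success or bfgs.success):
        raise ConvergenceError(
            "MAP optimizer failed to converge",
            diagnostics={"nelder_mead": nm, "bfgs": bfgs},
        )

    H = _fd_hessian(fun, best.x)
    # OFV is on the -2 log posterior scale: cov = 2 * H^-1
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = 2.0 * np.linalg.pinv(H)
    cov = 0.5 * (cov + cov.T)
    return PosteriorEstimate(
        model_id=model.model_id,
        eta_mode=best.x,
        covariance=cov,
        objective_value=float(best.fun),
        n_obs_used=len(obs),
        typical=typical,
    )


def _ensure_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < 0:
        warnings.warn(
            "posterior covariance not positive semi-definite; "
            "clipping eigenvalues at 1e-10",
            stacklevel=3,
        )
        vals = np.clip(vals, 1e-10, None)
        cov = vecs @ np.diag(vals) @ vecs.T
    return cov


def sample_etas(
    posterior: PosteriorEstimate,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    cov = _ensure_psd(posterior.covariance)
    return rng.multivariate_normal(posterior.eta_mode, cov, size=n,
                                   method="eigh")


def attainment_probability(
    model: PopulationModel,
    posterior: PosteriorEstimate,
    regimen: Regimen,
    auc_threshold: float = 400.0,
    trough_threshold: float = 20.0,
    mic: float = 1.0,
    config: RunConfig = DEFAULT_CONFIG,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo P(AUC24,ss/MIC > threshold) and P(trough,ss > threshold).

    Draws eta from the Laplace posterior (N = config.mc_samples, seeded) and
    evaluates the closed-form steady-state metrics per draw.
    """
    if auc_threshold <= 0 or trough_threshold <= 0:
        raise ValueError("thresholds must be positive")
    rng = np.random.default_rng(config.mc_seed if seed is None else seed)
    etas = sample_etas(posterior, config.mc_samples, rng)
    names = model.eta_names
    tv = posterior.typical
    factors = {name: np.exp(etas[:, i]) for i, name in enumerate(names)}
    cl = tv.cl * factors.get("CL", 1.0)
    v = tv.v * factors.get("V", factors.get("V1", 1.0))
    v2 = None if tv.v2 is None else tv.v2 * factors.get("V2", 1.0)
    q = None if tv.q is None else tv.q * factors.get("Q", 1.0)
    auc = steady_state_auc24(cl, regimen) / mic
    trough = steady_state_trough(cl, v, v2, q, regimen)
    return float(np.mean(auc > auc_threshold)), float(np.mean(trough > trough_threshold))
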