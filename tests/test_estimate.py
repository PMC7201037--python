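"""MAP estimation: objective, mode finding, posterior, attainment engine."""
import numpy as np
import pytest
from scipy.optimize import brentq

from vancomipd import (
    Regimen,
    TdmObservation,
    attainment_probability,
    fit_map,
    map_objective,
)
from vancomipd.course import predict_course
from vancomipd.estimate import PosteriorEstimate

from conftest import make_course, noise_free_observations


class TestMapObjective:
    def test_prior_mode_with_no_data_is_zero(self, neonate_cov, neonatal_model):
        course = make_course(neonate_cov, n_doses=4)
        assert map_objective([0.0, 0.0], neonatal_model, course) == 0.0

    def test_observation_on_typical_curve_keeps_mode_near_prior(
        self, neonate_cov, neonatal_model
    ):
        """A datum on the typical curve leaves the mode essentially at eta = 0.

        The residual and prior gradients both vanish there; the only pull
        away comes from the ln g^2 variance-sensitivity term, which is of
        order prop^2 (~0.04), so the mode stays within that order of zero
        and improves on the prior mode.
        """
        course = make_course(neonate_cov, n_doses=4)
        course.observations = noise_free_observations(course, [0.0, 0.0], [11.9])
        post = fit_map(neonatal_model, course)
        np.testing.assert_allclose(post.eta_mode, 0.0, atol=0.05)
        assert post.objective_value <= map_objective(
            [0.0, 0.0], neonatal_model, course
        ) + 1e-12

    def test_prior_term_quadratic(self, neonate_cov, neonatal_model):
        course = make_course(neonate_cov, n_doses=2)
        omega = neonatal_model.omegas()
        eta = np.array([0.3, -0.2])
        assert map_objective(eta, neonatal_model, course) == pytest.approx(
            float(np.sum(eta**2 / omega**2)), rel=1e-12
        )


class TestFitMap:
    def test_no_observations_returns_prior(self, neonate_cov, neonatal_model):
        post = fit_map(neonatal_model, make_course(neonate_cov, n_doses=4))
        np.testing.assert_array_equal(post.eta_mode, 0.0)
        omega = neonatal_model.omegas()
        np.testing.assert_allclose(post.covariance, np.diag(omega**2))
        assert post.n_obs_used == 0
        assert post.objective_value == 0.0

    def test_excluded_and_predose_observations_ignored(
        self, neonate_cov, neonatal_model
    ):
        course = make_course(neonate_cov, n_doses=4)
        course.observations = [
            TdmObservation(11.9, 15.0, flag="excluded"),
        ]
        post = fit_map(neonatal_model, course)
        assert post.n_obs_used == 0
        shifted = make_course(neonate_cov, n_doses=4)
        shifted.doses = [
            type(d)(d.start_time_h + 5.0, d.amount_mg, d.infusion_duration_h)
            for d in shifted.doses
        ]
        shifted.observations = [TdmObservation(1.0, 5.0)]
        with pytest.warns(UserWarning, match="precedes the first dose"):
            post = fit_map(neonatal_model, shifted)
        assert post.n_obs_used == 0

    def test_noise_free_round_trip(self, neonate_cov, neonatal_model):
        """Simulate-then-fit recovers the true random effects.

        The extended-least-squares objective retains an O(prop^2) offset at
        noise-free data through its ln g^2 term, so recovery is asserted to
        that order, plus the defining mode property: no eta (including the
        truth) beats the fitted mode's objective.
        """
        true_eta = np.array([0.3, -0.1])
        course = make_course(neonate_cov, n_doses=8)
        times = np.concatenate(
            [np.array([1.0, 4.0, 11.9]) + 12 * i for i in range(8)]
        )
        course.observations = noise_free_observations(course, true_eta, times)
        post = fit_map(neonatal_model, course)
        np.testing.assert_allclose(post.eta_mode, true_eta, atol=0.1)
        assert post.objective_value <= map_objective(
            true_eta, neonatal_model, course
        ) + 1e-9

    def test_deterministic(self, neonate_cov, neonatal_model):
        course = make_course(neonate_cov, n_doses=6)
        course.observations = [TdmObservation(35.9, 14.2)]
        a = fit_map(neonatal_model, course)
        b = fit_map(neonatal_model, course)
        np.testing.assert_array_equal(a.eta_mode, b.eta_mode)

    def test_single_observation_shrinks_toward_prior(
        self, neonate_cov, neonatal_model
    ):
        """The MAP mode under-reaches the eta that interpolates the datum.

        Along the mode's direction, scale s * eta_mode until the prediction
        passes through the observation (root-finding oracle); shrinkage means
        the required s exceeds 1.
        """
        rng = np.random.default_rng(11)
        n_shrunk = 0
        for _ in range(20):
            course = make_course(neonate_cov, n_doses=6)
            y = float(rng.uniform(5.0, 30.0))
            t_obs = float(rng.uniform(20.0, 60.0))
            course.observations = [TdmObservation(t_obs, y)]
            post = fit_map(neonatal_model, course)
            direction = post.eta_mode
            if np.linalg.norm(direction) < 1e-8:
                continue

            def gap(s):
                return float(
                    predict_course(course, s * direction, [t_obs])[0]
                ) - y

            s_hi = next((s for s in (2.0, 4.0, 8.0, 16.0)
                         if np.sign(gap(s)) != np.sign(gap(0.0))), None)
            if s_hi is None:
                continue  # datum unreachable along this direction
            s_star = brentq(gap, 0.0, s_hi, xtol=1e-10)
            assert s_star > 1.0
            n_shrunk += 1
        assert n_shrunk >= 12  # nearly every random case is informative


def test_two_compartment_fit_and_forecast():
    """The four-random-effect adolescent model fits and forecasts end to end."""
    from vancomipd import CovariateRecord, get_model
    from vancomipd.course import PatientCourse

    model = get_model("thomson")
    cov = CovariateRecord(weight_kg=55.0, serum_creatinine_mg_dl=0.7,
                          chronological_age_days=14 * 365.25, height_cm=165.0)
    reg = Regimen(850.0, 8.0, 1.0)
    course = PatientCourse("teen", "thomson", [cov], reg.doses(5))
    times = [9.0, 23.9]
    course.observations = noise_free_observations(
        course, [0.2, -0.1, 0.3, 0.1], times
    )
    post = fit_map(model, course)
    assert post.eta_mode.shape == (4,)
    assert post.n_obs_used == 2
    vals = np.linalg.eigvalsh(0.5 * (post.covariance + post.covariance.T))
    assert vals.min() > -1e-8  # Laplace covariance is (numerically) PSD
    p_auc, p_trough = attainment_probability(model, post, reg, seed=2)
    assert 0.0 <= p_auc <= 1.0 and 0.0 <= p_trough <= 1.0


class TestAttainmentProbability:
    def _point_posterior(self, neonatal_model, neonate_cov, eta=(0.0, 0.0),
                         cov_scale=0.0):
        from vancomipd import typical_parameters

        tv = typical_parameters("frymoyer_neonatal", neonate_cov)
        n = len(neonatal_model.eta_names)
        return PosteriorEstimate(
            model_id="frymoyer_neonatal",
            eta_mode=np.asarray(eta, dtype=float),
            covariance=cov_scale * np.eye(n),
            objective_value=0.0,
            n_obs_used=0,
            typical=tv,
        )

    def test_degenerate_posterior_gives_certainty(
        self, neonatal_model, neonate_cov
    ):
        post = self._point_posterior(neonatal_model, neonate_cov)
        # typical CL = 0.1725 L/h; 45 mg q12h -> AUC24 = 90/0.1725 = 521.7
        p_auc, p_trough = attainment_probability(
            neonatal_model, post, Regimen(45.0, 12.0, 1.0), auc_threshold=400.0
        )
        assert p_auc == 1.0
        p_auc_hi, _ = attainment_probability(
            neonatal_model, post, Regimen(45.0, 12.0, 1.0), auc_threshold=600.0
        )
        assert p_auc_hi == 0.0

    def test_monotone_in_threshold(self, neonatal_model, neonate_cov):
        post = self._point_posterior(neonatal_model, neonate_cov,
                                     cov_scale=0.05)
        probs = [
            attainment_probability(
                neonatal_model, post, Regimen(45.0, 12.0, 1.0),
                auc_threshold=thr, seed=5,
            )[0]
            for thr in (300.0, 400.0, 500.0, 600.0)
        ]
        assert probs == sorted(probs, reverse=True)

    def test_seeded_reproducibility(self, neonatal_model, neonate_cov):
        post = self._point_posterior(neonatal_model, neonate_cov,
                                     cov_scale=0.04)
        reg = Regimen(45.0, 12.0, 1.0)
        a = attainment_probability(neonatal_model, post, reg, seed=3)
        b = attainment_probability(neonatal_model, post, reg, seed=3)
        assert a == b

    def test_across_seed_variation_within_binomial_error(
        self, neonatal_model, neonate_cov
    ):
        post = self._point_posterior(neonatal_model, neonate_cov,
                                     cov_scale=0.04)
        reg = Regimen(45.0, 12.0, 1.0)
        ps = np.array([
            attainment_probability(neonatal_model, post, reg, seed=s)[0]
            for s in range(8)
        ])
        p = ps.mean()
        se = np.sqrt(p * (1 - p) / 10_000)
        assert ps.std() <= 3 * se

    def test_non_psd_covariance_regularized_with_warning(
        self, neonatal_model, neonate_cov
    ):
        post = self._point_posterior(neonatal_model, neonate_cov)
        bad = PosteriorEstimate(
            model_id=post.model_id,
            eta_mode=post.eta_mode,
            covariance=np.array([[0.04, 0.0], [0.0, -0.01]]),
            objective_value=0.0,
            n_obs_used=0,
            typical=post.typical,
        )
        with pytest.warns(UserWarning, match="positive semi-definite"):
            p_auc, _ = attainment_probability(
                neonatal_model, bad, Regimen(45.0, 12.0, 1.0)
            )
        assert 0.0 <= p_auc <= 1.0
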