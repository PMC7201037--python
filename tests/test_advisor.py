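"""Reference table, custom-regimen evaluation, dose search, empiric dosing."""
import numpy as np
import pytest

from vancomipd import (
    NoFeasibleRegimenError,
    Regimen,
    RunConfig,
    SearchConstraints,
    TargetSpec,
    CovariateRecord,
    empiric_starting_dose,
    evaluate_custom_regimen,
    find_regimen,
    fit_map,
    reference_table,
    schwartz_egfr,
    steady_state_metrics,
    tdm_advice,
)
from vancomipd.advisor import REFERENCE_MULTIPLIERS
from vancomipd.dynamics import steady_state_trough

from conftest import make_course


@pytest.fixture
def neonate_posterior(neonate_cov, neonatal_model):
    return fit_map(neonatal_model, make_course(neonate_cov, n_doses=4))


class TestSchwartzEgfr:
    def test_worked_examples(self):
        assert schwartz_egfr(105.0, 0.4) == pytest.approx(108.4, abs=0.05)
        assert schwartz_egfr(100.0, 1.0) == pytest.approx(41.3, rel=1e-12)

    def test_inverse_proportional_to_creatinine(self):
        assert schwartz_egfr(120.0, 0.3) == pytest.approx(
            2 * schwartz_egfr(120.0, 0.6), rel=1e-12
        )

    def test_missing_height_is_an_error(self):
        with pytest.raises(Exception, match="height"):
            schwartz_egfr(0.0, 0.5)


class TestReferenceTable:
    def test_row_set_and_identity_row(self, neonatal_model, neonate_posterior):
        current = Regimen(45.0, 12.0, 1.0)
        table = reference_table(neonatal_model, neonate_posterior, current)
        assert tuple(r.multiplier for r in table.rows) == REFERENCE_MULTIPLIERS
        base = steady_state_metrics(neonate_posterior.realized(), current)
        row = table.row(1.00)
        assert row.exposure.auc24_ss == base.auc24_ss
        assert row.exposure.trough_ss == base.trough_ss
        assert row.regimen == current

    def test_auc_scales_linearly_with_multiplier(
        self, neonatal_model, neonate_posterior
    ):
        table = reference_table(neonatal_model, neonate_posterior,
                                Regimen(45.0, 12.0, 1.0))
        assert table.row(1.30).exposure.auc24_ss == pytest.approx(
            1.30 * table.row(1.00).exposure.auc24_ss, rel=1e-12
        )

    def test_overexposure_probability_nondecreasing_in_dose(
        self, neonatal_model, neonate_posterior
    ):
        table = reference_table(neonatal_model, neonate_posterior,
                                Regimen(45.0, 12.0, 1.0))
        p = [r.exposure.p_auc24_gt_400 for r in table.rows]
        assert all(b >= a for a, b in zip(p, p[1:]))

    def test_custom_regimen_reproduces_identity_row(
        self, neonatal_model, neonate_posterior
    ):
        current = Regimen(45.0, 12.0, 1.0)
        table = reference_table(neonatal_model, neonate_posterior, current)
        custom = evaluate_custom_regimen(neonatal_model, neonate_posterior,
                                         current)
        assert custom == table.row(1.00).exposure

    def test_infusion_longer_than_interval_rejected(self):
        with pytest.raises(Exception):
            Regimen(100.0, 6.0, 7.0)


class TestCustomRegimenComparisons:
    def test_equal_daily_dose_same_auc_different_trough(
        self, neonate_posterior
    ):
        p = neonate_posterior.realized()
        q6 = steady_state_metrics(p, Regimen(30.0, 6.0, 1.0))
        q8 = steady_state_metrics(p, Regimen(40.0, 8.0, 1.0))
        assert q6.auc24_ss == pytest.approx(q8.auc24_ss, rel=1e-12)
        assert q6.trough_ss != pytest.approx(q8.trough_ss, rel=1e-3)

    @pytest.mark.parametrize("daily", [80.0, 120.0, 200.0])
    def test_trough_rises_as_interval_shortens(self, neonate_posterior, daily):
        p = neonate_posterior.realized()
        troughs = [
            steady_state_metrics(
                p, Regimen(daily * tau / 24.0, tau, 1.0)
            ).trough_ss
            for tau in (24.0, 12.0, 8.0, 6.0)
        ]
        assert troughs == sorted(troughs)


class TestFindRegimen:
    def test_auc_target_satisfied(self, neonatal_model, neonate_posterior):
        target = TargetSpec(metric="auc24_over_mic", lower=400, upper=600)
        reg = find_regimen(
            neonatal_model, neonate_posterior, target,
            SearchConstraints(dose_increment_mg=1.0, max_dose_mg=300.0),
        )
        cl = neonate_posterior.realized().cl
        assert 400 <= reg.daily_dose_mg / cl <= 600

    def test_band_containing_current_returns_current(
        self, neonatal_model, neonate_posterior
    ):
        cl = neonate_posterior.realized().cl
        current = Regimen(45.0, 12.0, 1.0)
        auc = current.daily_dose_mg / cl
        # a band centered exactly on the current regimen's prediction
        target = TargetSpec(lower=auc - 10, upper=auc + 10)
        reg = find_regimen(
            neonatal_model, neonate_posterior, target,
            SearchConstraints(intervals_h=(12.0,), dose_increment_mg=1.0,
                              max_dose_mg=300.0),
        )
        assert reg.interval_h == 12.0
        assert reg.dose_mg == pytest.approx(current.dose_mg, abs=1.0)

    def test_daily_dose_doubles_with_target(self, neonatal_model,
                                            neonate_posterior):
        c = SearchConstraints(dose_increment_mg=1.0, max_dose_mg=600.0)
        lo = find_regimen(neonatal_model, neonate_posterior,
                          TargetSpec(lower=250, upper=350), c)
        hi = find_regimen(neonatal_model, neonate_posterior,
                          TargetSpec(lower=550, upper=650), c)
        assert hi.daily_dose_mg == pytest.approx(2 * lo.daily_dose_mg,
                                                 rel=0.02)

    def test_returned_regimen_is_grid_optimal(self, neonatal_model,
                                              neonate_posterior):
        """Exhaustive re-check: no grid point is closer to the band midpoint."""
        target = TargetSpec(lower=400, upper=600)
        c = SearchConstraints(intervals_h=(8.0, 12.0),
                              dose_increment_mg=5.0, max_dose_mg=200.0)
        reg = find_regimen(neonatal_model, neonate_posterior, target, c)
        cl = neonate_posterior.realized().cl
        best = abs(reg.daily_dose_mg / cl - target.midpoint)
        for tau in c.intervals_h:
            for dose in np.arange(5.0, 201.0, 5.0):
                metric = dose * 24.0 / tau / cl
                if target.lower <= metric <= target.upper:
                    assert best <= abs(metric - target.midpoint) + 1e-9

    def test_trough_target_search(self, neonatal_model, neonate_posterior):
        target = TargetSpec(metric="trough", lower=10.0, upper=15.0)
        reg = find_regimen(
            neonatal_model, neonate_posterior, target,
            SearchConstraints(dose_increment_mg=1.0, max_dose_mg=300.0),
        )
        p = neonate_posterior.realized()
        trough = float(steady_state_trough(p.cl, p.v, p.v2, p.q, reg))
        assert 10.0 <= trough <= 15.0

    def test_infeasible_band_raises(self, neonatal_model, neonate_posterior):
        with pytest.raises(NoFeasibleRegimenError, match="no feasible regimen"):
            find_regimen(
                neonatal_model, neonate_posterior,
                TargetSpec(lower=40000, upper=50000),
                SearchConstraints(dose_increment_mg=25.0, max_dose_mg=100.0),
            )

    def test_tie_breaks_prefer_longer_interval(self, neonatal_model,
                                               neonate_posterior):
        # with 1 mg rounding the AUC metric can hit the midpoint on every
        # interval, so the tie must resolve to the longest one
        reg = find_regimen(
            neonatal_model, neonate_posterior, TargetSpec(lower=400, upper=600),
            SearchConstraints(intervals_h=(6.0, 8.0, 12.0, 24.0),
                              dose_increment_mg=1.0, max_dose_mg=300.0),
        )
        assert reg.interval_h == 24.0


class TestEmpiricStartingDose:
    def test_child_guideline_dose(self, child_cov):
        start = empiric_starting_dose(child_cov, "le_pediatric")
        assert start.basis == "guideline_weight_based"
        # 15 mg/kg x 19.1 kg = 286.5 mg, rounded to the 25 mg grid
        assert start.regimen.dose_mg == 275.0
        assert start.regimen.interval_h == 6.0
        assert start.flags == ()

    def test_adolescent_gets_q8h(self):
        teen = CovariateRecord(weight_kg=55.0, serum_creatinine_mg_dl=0.7,
                               chronological_age_days=14 * 365.25,
                               height_cm=165.0)
        start = empiric_starting_dose(teen, "le_pediatric")
        assert start.regimen.interval_h == 8.0
        # 15 x 55 = 825 mg sits mid-grid; half-up rounding on the 50 mg grid
        assert start.regimen.dose_mg == pytest.approx(850.0)

    def test_reduced_renal_function_extends_interval(self):
        child = CovariateRecord(weight_kg=19.1, serum_creatinine_mg_dl=1.0,
                                chronological_age_days=6 * 365.25,
                                height_cm=105.0)
        start = empiric_starting_dose(child, "le_pediatric")
        assert start.regimen.interval_h == 12.0
        assert any("reduced renal function" in f for f in start.flags)
        assert start.regimen.dose_mg == 275.0  # still 15 mg/kg

    def test_missing_height_flags_unverified_renal_function(self):
        child = CovariateRecord(weight_kg=19.1, serum_creatinine_mg_dl=0.4,
                                chronological_age_days=6 * 365.25)
        start = empiric_starting_dose(child, "le_pediatric")
        assert any("renal function unverified" in f for f in start.flags)

    def test_neonate_model_based_start_hits_target(
        self, neonate_cov, neonatal_model, neonate_posterior
    ):
        cfg = RunConfig()
        start = empiric_starting_dose(neonate_cov, "frymoyer_neonatal", cfg)
        assert start.basis == "model_based"
        exposure = evaluate_custom_regimen(neonatal_model, neonate_posterior,
                                           start.regimen, cfg)
        assert cfg.target.lower <= exposure.auc24_ss <= cfg.target.upper

    def test_child_dose_ignores_irrelevant_covariates(self, child_cov):
        base = empiric_starting_dose(child_cov, "le_pediatric")
        from dataclasses import replace

        other = replace(child_cov, sex="F")
        assert empiric_starting_dose(other, "le_pediatric").regimen == \
            base.regimen


class TestTdmAdvice:
    def test_default_advice(self, child_cov):
        assert "before the fourth dose" in tdm_advice([child_cov])

    def test_low_egfr_advises_earlier_draw(self):
        child = CovariateRecord(weight_kg=19.1, serum_creatinine_mg_dl=1.0,
                                chronological_age_days=6 * 365.25,
                                height_cm=105.0)
        assert "earlier" in tdm_advice([child])

    def test_rising_creatinine_advises_earlier_draw(self, child_cov):
        from dataclasses import replace

        later = replace(child_cov, serum_creatinine_mg_dl=0.8,
                        effective_time_h=24.0, height_cm=None)
        first = replace(child_cov, height_cm=None)
        assert "earlier" in tdm_advice([first, later])
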