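"""Clinical definitions: BP summary, cascade categories, eGFR, comorbidities."""

import numpy as np
import pytest

from frailcascade.clinical import (BPSummary, classify_bp, classify_diabetes,
                                   classify_dyslipidemia, classify_lifestyle,
                                   control_flags, egfr_ckd_epi, is_ckd,
                                   is_treated, summarize_bp, cascade_status,
                                   BP_HTN, BP_NORMAL, BP_PRE_HTN)
from frailcascade.cohort import BPReading, RunConfig


def _readings(*pairs):
    return [BPReading(s, d) for s, d in pairs]


class TestSummarizeBP:
    def test_identical_readings(self):
        bp = summarize_bp(_readings((130, 80), (130, 80), (130, 80)))
        assert (bp.sbp, bp.dbp, bp.pulse_pressure) == (130, 80, 50)

    def test_mean_of_second_and_third_only(self):
        bp = summarize_bp(_readings((160, 100), (130, 80), (120, 70)))
        assert (bp.sbp, bp.dbp, bp.pulse_pressure) == (125, 75, 50)

    def test_first_reading_never_matters(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            d = rng.uniform(50, 110, 3)
            s = d + rng.uniform(10, 90, 3)
            base = summarize_bp(_readings(*zip(s, d)))
            s2, d2 = s.copy(), d.copy()
            s2[0], d2[0] = d2[0] + 200 * rng.random() + 1, 40 * rng.random() + 30
            perturbed = summarize_bp(_readings(*zip(s2, d2)))
            assert (perturbed.sbp, perturbed.dbp) == (base.sbp, base.dbp)

    def test_missing_reading_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_bp(_readings((130, 80), (None, None), (120, 70)))


class TestClassifyBP:
    def test_boundary_window_is_pre_htn(self, config):
        assert classify_bp(BPSummary(139.5, 89.5), False, config) == BP_PRE_HTN

    def test_sbp_threshold_inclusive(self, config):
        assert classify_bp(BPSummary(140.0, 70.0), False, config) == BP_HTN

    def test_medication_dominates_any_bp(self, config):
        for sbp in (100.0, 125.0, 139.9, 180.0):
            for dbp in (60.0, 85.0, 110.0):
                if sbp <= dbp:
                    continue
                assert classify_bp(BPSummary(sbp, dbp), True, config) == BP_HTN

    @pytest.mark.parametrize("sbp,dbp,and_result,or_result", [
        (125.0, 85.0, BP_PRE_HTN, BP_PRE_HTN),   # both components inside
        (125.0, 70.0, BP_NORMAL, BP_PRE_HTN),    # SBP inside only
        (110.0, 85.0, BP_NORMAL, BP_PRE_HTN),    # DBP inside only
        (110.0, 70.0, BP_NORMAL, BP_NORMAL),     # neither
    ])
    def test_prehtn_semantics_truth_table(self, sbp, dbp, and_result, or_result):
        cfg_and = RunConfig(prehtn_semantics="as_printed_and")
        cfg_or = RunConfig(prehtn_semantics="jnc7_or")
        assert classify_bp(BPSummary(sbp, dbp), False, cfg_and) == and_result
        assert classify_bp(BPSummary(sbp, dbp), False, cfg_or) == or_result


class TestTreatmentAndControl:
    def test_twenty_days_is_treated(self, config):
        assert is_treated(20, config)

    def test_nineteen_days_is_not(self, config):
        assert not is_treated(19, config)

    def test_missing_days_untreated(self, config):
        assert not is_treated(None, config)

    def test_days_out_of_range_error(self, config):
        with pytest.raises(ValueError):
            is_treated(35, config)

    @pytest.mark.parametrize("sbp,dbp,expect", [
        (149.0, 89.0, (True, True, True)),
        (150.0, 89.0, (False, True, False)),
        (133.1, 73.0, (True, True, True)),
    ])
    def test_control_boundaries(self, config, sbp, dbp, expect):
        f = control_flags(BPSummary(sbp, dbp), config)
        assert (f.controlled_sbp, f.controlled_dbp, f.controlled_composite) == expect

    def test_lowering_bp_never_loses_control(self, config):
        rng = np.random.default_rng(7)
        for _ in range(300):
            dbp = rng.uniform(50, 120)
            sbp = dbp + rng.uniform(10, 120)
            before = control_flags(BPSummary(sbp, dbp), config)
            lower = control_flags(
                BPSummary(sbp - rng.uniform(0, 30), dbp - rng.uniform(0, 20)),
                config)
            if before.controlled_composite:
                assert lower.controlled_composite

    def test_treated_implies_htn_in_cascade(self, make_record):
        rec = make_record({"antihypertensive_days_per_month": 25,
                           "on_antihypertensive_med": True})
        status = cascade_status(rec, RunConfig())
        assert status.bp_category == BP_HTN and status.treated
        assert status.controlled_composite  # 120/70 is under 150/90


class TestEgfr:
    def test_strictly_decreasing_in_creatinine(self):
        grid = np.linspace(0.3, 5.0, 60)
        for sex in ("male", "female"):
            vals = [egfr_ckd_epi(c, 75, sex) for c in grid]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_decreasing_in_age(self):
        vals = [egfr_ckd_epi(1.0, a, "male") for a in range(65, 100)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_doubling_creatinine_lowers_egfr(self):
        assert egfr_ckd_epi(2.0, 70, "male") < egfr_ckd_epi(1.0, 70, "male")

    def test_elderly_female_high_creatinine_is_ckd(self):
        egfr = egfr_ckd_epi(2.5, 80, "female")
        assert egfr < 60 and is_ckd(egfr)

    def test_ckd_agrees_with_threshold_everywhere(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            e = egfr_ckd_epi(rng.uniform(0.4, 4.0), rng.uniform(65, 95),
                             rng.choice(["male", "female"]))
            assert is_ckd(e) == (e < 60.0)

    def test_nonpositive_creatinine_error(self):
        with pytest.raises(ValueError):
            egfr_ckd_epi(0.0, 70, "male")


class TestDiabetesAndLipids:
    @pytest.mark.parametrize("glucose,expect", [
        (126.0, "diabetes"), (125.0, "igt"), (100.0, "igt"), (99.0, "normal"),
    ])
    def test_glucose_thresholds(self, glucose, expect):
        assert classify_diabetes(glucose, False, False) == expect

    def test_medication_or_diagnosis_is_diabetes(self):
        assert classify_diabetes(90.0, True, False) == "diabetes"
        assert classify_diabetes(None, False, True) == "diabetes"

    def test_all_missing_is_indeterminate(self):
        assert classify_diabetes(None, None, None) is None

    def test_hypercholesterolemia_at_240(self):
        flags = classify_dyslipidemia(240.0, 100.0, 50.0, False)
        assert flags.hypercholesterolemia and flags.any

    def test_hdl_boundary_not_low(self):
        assert not classify_dyslipidemia(200.0, 150.0, 40.0, False).any

    def test_lipid_medication_counts(self):
        assert classify_dyslipidemia(200.0, 150.0, 45.0, True).any


class TestLifestyle:
    def test_vigorous_three_twenty_is_exercise(self, make_record):
        rec = make_record({"vigorous_sessions_per_week": 3, "vigorous_minutes": 20.0,
                           "moderate_sessions_per_week": 0, "moderate_minutes": 0.0,
                           "walking_sessions_per_week": 0, "walking_minutes": 0.0})
        assert classify_lifestyle(rec)[1]

    def test_moderate_four_sessions_is_not(self, make_record):
        rec = make_record({"vigorous_sessions_per_week": 0, "vigorous_minutes": 0.0,
                           "moderate_sessions_per_week": 4, "moderate_minutes": 45.0,
                           "walking_sessions_per_week": 0, "walking_minutes": 0.0})
        assert not classify_lifestyle(rec)[1]

    def test_bmi_arithmetic(self, make_record):
        rec = make_record({"weight": 60.0, "height": 1.60})
        smoker, _, bmi, obesity = classify_lifestyle(rec)
        assert bmi == pytest.approx(23.4375)
        assert not obesity and not smoker

    def test_lifetime_packs_makes_smoker(self, make_record):
        rec = make_record({"smoker_current": False, "lifetime_packs_ge_5": True})
        assert classify_lifestyle(rec)[0]

    def test_missing_height_gives_missing_bmi(self, make_record):
        rec = make_record({"height": None})
        assert classify_lifestyle(rec)[2] is None
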