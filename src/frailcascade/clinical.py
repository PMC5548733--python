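"""Clinical status derivation: blood-pressure summary and hypertension cascade,
CKD-EPI eGFR, diabetes/dyslipidemia classification, and lifestyle factors.

All threshold values are injected from :class:`~frailcascade.cohort.RunConfig`
so that sensitivity analyses (e.g. a 140/90 vs 150/90 control target) are
one-line config edits, never code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cohort import ParticipantRecord, RunConfig

BP_NORMAL = "normal"
BP_PRE_HTN = "pre_htn"
BP_HTN = "htn"

DM_NORMAL = "normal"
DM_IGT = "igt"
DM_DIABETES = "diabetes"


@dataclass(frozen=True)
class BPSummary:
    """Final systolic/diastolic blood pressure: the mean of the second and
    third of three seated readings (the first is discarded as an
    accommodation reading)."""

    sbp: float
    dbp: float

    @property
    def pulse_pressure(self) -> float:
        return self.sbp - self.dbp


@dataclass(frozen=True)
class ControlFlags:
    controlled_sbp: bool
    controlled_dbp: bool

    @property
    def controlled_composite(self) -> bool:
        return self.controlled_sbp and self.controlled_dbp


@dataclass(frozen=True)
class HtnCascadeStatus:
    """One subject's position in the hypertension care cascade."""

    bp_category: str  # normal | pre_htn | htn
    treated: bool
    controlled_sbp: Optional[bool] = None    # defined only when treated
    controlled_dbp: Optional[bool] = None
    controlled_composite: Optional[bool] = None

    def __post_init__(self):
        if self.treated and self.bp_category != BP_HTN:
            raise ValueError("treated implies hypertensive")
        if self.treated:
            if self.controlled_composite != (self.controlled_sbp and self.controlled_dbp):
                raise ValueError("composite control must be SBP-control AND DBP-control")
        elif any(v is not None for v in (self.controlled_sbp, self.controlled_dbp,
                                         self.controlled_composite)):
            raise ValueError("control flags are defined only for treated subjects")


@dataclass
class DyslipidemiaFlags:
    hypercholesterolemia: bool
    hypertriglyceridemia: bool
    low_hdl: bool

    @property
    def any(self) -> bool:
        return self.hypercholesterolemia or self.hypertriglyceridemia or self.low_hdl


@dataclass
class ComorbidityProfile:
    diabetes_class: Optional[str]  # normal | igt | diabetes | None (indeterminate)
    dyslipidemia: Optional[DyslipidemiaFlags]
    egfr: Optional[float]  # mL/min/1.73 m^2
    ckd: Optional[bool]
    smoker: Optional[bool]
    exerciser: Optional[bool]
    bmi: Optional[float]  # kg/m^2
    obesity: Optional[bool]


def summarize_bp(readings) -> BPSummary:
    """Mean of the second and third readings; the first reading is ignored."""
    if len(readings) != 3 or any(r.is_missing for r in readings):
        raise ValueError("summarize_bp requires 3 complete readings "
                         "(incomplete records must be excluded upstream)")
    sbp = (readings[1].sbp + readings[2].sbp) / 2.0
    dbp = (readings[1].dbp + readings[2].dbp) / 2.0
    return BPSummary(sbp=sbp, dbp=dbp)


def classify_bp(bp: BPSummary, on_med: bool, config: RunConfig) -> str:
    """Hypertension iff SBP >= 140 or DBP >= 90 (component-wise OR) or on
    antihypertensive medication.  Among non-hypertensives, pre-hypertension
    follows the configured semantics:

    - ``as_printed_and`` (default): 120 <= SBP < 140 *and* 80 <= DBP < 90;
    - ``jnc7_or``: either component inside its window (conventional reading).
    """
    if on_med or bp.sbp >= config.htn_sbp_threshold or bp.dbp >= config.htn_dbp_threshold:
        return BP_HTN
    sbp_in = 120.0 <= bp.sbp < config.htn_sbp_threshold
    dbp_in = 80.0 <= bp.dbp < config.htn_dbp_threshold
    if config.prehtn_semantics == "as_printed_and":
        pre = sbp_in and dbp_in
    else:  # jnc7_or
        pre = sbp_in or dbp_in
    return BP_PRE_HTN if pre else BP_NORMAL


def is_treated(days: Optional[int], config: RunConfig = None) -> bool:
    """Treated iff taking antihypertensive medication >= 20 days per month.

    Missing medication-days count as untreated.
    """
    if days is None:
        return False
    if not (0 <= days <= 31):
        raise ValueError(f"medication days/month outside 0-31: {days}")
    days_min = config.treatment_days_min if config is not None else 20
    return days >= days_min


def control_flags(bp: BPSummary, config: RunConfig) -> ControlFlags:
    """BP control at the (strict) target: SBP < 150 and DBP < 90 mmHg."""
    return ControlFlags(
        controlled_sbp=bp.sbp < config.control_sbp,
        controlled_dbp=bp.dbp < config.control_dbp,
    )


def cascade_status(record: ParticipantRecord, config: RunConfig) -> HtnCascadeStatus:
    """Derive the full care-cascade position for one (non-excluded) record."""
    bp = summarize_bp(record.bp_readings)
    treated = is_treated(record.antihypertensive_days_per_month, config)
    on_med = bool(record.on_antihypertensive_med) or treated
    category = classify_bp(bp, on_med, config)
    if not treated:
        return HtnCascadeStatus(bp_category=category, treated=False)
    flags = control_flags(bp, config)
    return HtnCascadeStatus(
        bp_category=category,
        treated=True,
        controlled_sbp=flags.controlled_sbp,
        controlled_dbp=flags.controlled_dbp,
        controlled_composite=flags.controlled_composite,
    )


# ---------------------------------------------------------------------------
# CKD-EPI (2009, creatinine) eGFR

_CKD_EPI = {
    # sex: (kappa, alpha, sex_factor)
    "female": (0.7, -0.329, 1.018),
    "male": (0.9, -0.411, 1.0),
}


def egfr_ckd_epi(creatinine: float, age: float, sex: str) -> float:
    """CKD-EPI 2009 creatinine equation (mL/min/1.73 m^2).

    eGFR = 141 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-1.209
             * 0.993^age * 1.018 [female]

    with k = 0.7 (F) / 0.9 (M) and alpha = -0.329 (F) / -0.411 (M).
    The race coefficient is fixed at 1.
    """
    if creatinine is None or creatinine <= 0:
        raise ValueError("creatinine must be positive")
    if sex not in _CKD_EPI:
        raise ValueError(f"sex must be male or female, got {sex!r}")
    kappa, alpha, sex_factor = _CKD_EPI[sex]
    ratio = creatinine / kappa
    return (141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209
            * 0.993 ** age * sex_factor)


def is_ckd(egfr: float) -> bool:
    """Chronic kidney disease iff eGFR < 60 mL/min/1.73 m^2."""
    return egfr < 60.0


def classify_diabetes(fasting_glucose: Optional[float],
                      on_glucose_med_or_insulin: Optional[bool],
                      physician_dx: Optional[bool]) -> Optional[str]:
    """Diabetes iff fasting glucose >= 126 mg/dL, on hypoglycemic
    medication/insulin, or physician-diagnosed; otherwise impaired glucose
    tolerance for 100 <= glucose <= 125 (both bounds inclusive); otherwise
    normal.  Returns ``None`` (indeterminate) when every input is missing.
    """
    if on_glucose_med_or_insulin or physician_dx:
        return DM_DIABETES
    if fasting_glucose is None:
        if on_glucose_med_or_insulin is None and physician_dx is None:
            return None  # indeterminate: no glucose, no flags answered
        return DM_NORMAL
    if fasting_glucose >= 126.0:
        return DM_DIABETES
    if 100.0 <= fasting_glucose <= 125.0:
        return DM_IGT
    return DM_NORMAL


def classify_dyslipidemia(total_cholesterol: Optional[float],
                          triglyceride: Optional[float],
                          hdl_cholesterol: Optional[float],
                          on_lipid_med: Optional[bool]) -> DyslipidemiaFlags:
    """Component flags: total cholesterol >= 240 mg/dL or on lipid
    medication; triglyceride >= 200 mg/dL; HDL < 40 mg/dL.  Dyslipidemia is
    any component."""
    if (total_cholesterol is None and triglyceride is None
            and hdl_cholesterol is None and on_lipid_med is None):
        raise ValueError("need at least one lipid value or the medication flag")
    return DyslipidemiaFlags(
        hypercholesterolemia=bool(
            (total_cholesterol is not None and total_cholesterol >= 240.0)
            or on_lipid_med),
        hypertriglyceridemia=bool(triglyceride is not None and triglyceride >= 200.0),
        low_hdl=bool(hdl_cholesterol is not None and hdl_cholesterol < 40.0),
    )


def is_exerciser(record: ParticipantRecord) -> Optional[bool]:
    """Regular exercise: vigorous activity >= 3 sessions/week of >= 20 min,
    or moderate activity or walking >= 5 sessions/week of >= 30 min."""
    fields = (record.vigorous_sessions_per_week, record.vigorous_minutes,
              record.moderate_sessions_per_week, record.moderate_minutes,
              record.walking_sessions_per_week, record.walking_minutes)
    if all(f is None for f in fields):
        return None

    def meets(sessions, minutes, min_sessions, min_minutes):
        return (sessions is not None and minutes is not None
                and sessions >= min_sessions and minutes >= min_minutes)

    return (meets(record.vigorous_sessions_per_week, record.vigorous_minutes, 3, 20)
            or meets(record.moderate_sessions_per_week, record.moderate_minutes, 5, 30)
            or meets(record.walking_sessions_per_week, record.walking_minutes, 5, 30))


def classify_lifestyle(record: ParticipantRecord, obesity_bmi_cutoff: float = 25.0):
    """Smoking (>= 5 lifetime packs or current), exercise, BMI, obesity.

    Returns ``(smoker, exerciser, bmi, obesity)``; BMI and obesity are
    ``None`` when height or weight is missing.
    """
    smoker = None
    if record.smoker_current is not None or record.lifetime_packs_ge_5 is not None:
        smoker = bool(record.smoker_current) or bool(record.lifetime_packs_ge_5)
    bmi = obesity = None
    if record.height is not None and record.weight is not None and record.height > 0:
        bmi = record.weight / record.height ** 2
        obesity = bmi >= obesity_bmi_cutoff
    return smoker, is_exerciser(record), bmi, obesity


def comorbidity_profile(record: ParticipantRecord,
                        obesity_bmi_cutoff: float = 25.0) -> ComorbidityProfile:
    """Derive every comorbidity/lifestyle status used by the analyses."""
    egfr = ckd = None
    if record.creatinine is not None and record.creatinine > 0:
        egfr = egfr_ckd_epi(record.creatinine, record.age, record.sex)
        ckd = is_ckd(egfr)
    try:
        dys = classify_dyslipidemia(record.total_cholesterol, record.triglyceride,
                                    record.hdl_cholesterol, record.on_lipid_med)
    except ValueError:
        dys = None
    smoker, exerciser, bmi, obesity = classify_lifestyle(record, obesity_bmi_cutoff)
    return ComorbidityProfile(
        diabetes_class=classify_diabetes(record.fasting_glucose,
                                         record.on_glucose_med_or_insulin,
                                         record.physician_dx_diabetes),
        dyslipidemia=dys,
        egfr=egfr,
        ckd=ckd,
        smoker=smoker,
        exerciser=exerciser,
        bmi=bmi,
        obesity=obesity,
    )
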