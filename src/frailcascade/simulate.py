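"""Seeded generator of survey-like elderly cohorts with planted
frailty-hypertension structure, plus its analytic (quadrature) expectation.

A single standard-normal liability ``z`` drives everything: the 40
non-blood-pressure deficit items share one logistic loading
``P(deficit | z) = sigma(a + b z)``; hypertension, treatment-given-HTN and
control-given-treatment are Bernoulli with logits linear in ``z`` (control
decreasing); and the summary blood pressure is drawn from
status-consistent truncated normals whose means move toward *both* extremes
as ``z`` grows (quadratic curvature), planting the U-shaped mean-FI vs BP
profile.  Readings two and three are constructed symmetric about the drawn
summary value, so the analysis pipeline recovers the planted cascade states
exactly; reading one carries independent noise and is discarded downstream.

``expected_cascade`` integrates the same model over the liability
distribution (conditioning on the blood-pressure status category, whose
truncated-normal bands feed the two BP deficit items) and serves as the
oracle for large-n simulation agreement.

Default numeric parameters are calibration goals for the marginal class
fractions (~0.17/0.39/0.44) and class-wise prevalence/treatment/control
gradients (~0.49/0.61/0.68, ~0.73/0.78/0.84, ~0.88/0.81/0.78); they make
no claim of distributional fidelity to any real survey.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import binom, norm, truncnorm

from .cohort import BPReading, ParticipantRecord
from .frailty import DeficitCodebook, default_codebook

# status categories; all but non_htn are hypertensive
CAT_NON = "non_htn"
CAT_UNT_S = "untreated_sbp"
CAT_UNT_D = "untreated_dbp"
CAT_CTL = "controlled"
CAT_UNC_S = "uncontrolled_sbp"
CAT_UNC_D = "uncontrolled_dbp"
CAT_UNC_B = "uncontrolled_both"
CATEGORIES = [CAT_NON, CAT_UNT_S, CAT_UNT_D, CAT_CTL, CAT_UNC_S, CAT_UNC_D, CAT_UNC_B]
HTN_CATS = frozenset(CATEGORIES[1:])
TREATED_CATS = frozenset([CAT_CTL, CAT_UNC_S, CAT_UNC_D, CAT_UNC_B])

N_POOLED_ITEMS = 40  # all codebook items except the two BP-derived ones

CLASSES = ["robust", "pre_frail", "frail"]
# FI boundaries in half-score units out of 42 items (FI = t/84):
# robust t <= 8 (8/84 = 0.0952), pre-frail t <= 17 (17/84 = 0.2024)
_T_ROBUST, _T_PREFRAIL = 8, 17


@dataclass
class GeneratorParams:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n: int = 4352
    seed: int = 0
    # demographics
    age_mean: float = 72.6
    age_sd: float = 5.4
    age_min: float = 65.0
    age_z_slope: float = 0.8          # years per liability unit
    male_logit0: float = -0.26        # P(male | z) = sigma(l0 + l1 z)
    male_logit_slope: float = -0.45
    # shared deficit loading of the 40 pooled items: P = sigma(a + b z)
    deficit_intercept: float = -1.4187
    deficit_slope: float = 0.546
    # cascade logits
    htn_logit0: float = 0.4989        # P(HTN | z) = sigma(c0 + c1 z)
    htn_logit_slope: float = 0.2756
    treat_logit0: float = 1.4348      # P(treated | HTN, z) = sigma(d0 + d1 z)
    treat_logit_slope: float = 0.6278
    control_logit0: float = 1.4129    # P(controlled | treated, z) = sigma(e0 - e1 z)
    control_logit_slope: float = 0.0388
    # blood-pressure structure (mmHg)
    sbp_curvature: float = 4.0        # quadratic z -> BP-extremes term
    dbp_curvature: float = 2.5
    reading1_noise_sd: float = 6.0
    within_pair_noise_sd: float = 4.0
    untreated_dbp_fraction: float = 0.2
    uncontrolled_split: tuple = (0.70, 0.15, 0.15)  # SBP-only, DBP-only, both
    # planted missingness (for the exclusion fixture)
    n_missing_bp: int = 0
    n_missing_questionnaire: int = 0


def exclusion_fixture_params(seed: int = 0) -> GeneratorParams:
    """The exclusion-filter fixture: 4,557 elderly with 10 BP-missing and
    195 medication-questionnaire-missing records planted (4,352 analysable)."""
    return GeneratorParams(n=4557, seed=seed, n_missing_bp=10,
                           n_missing_questionnaire=195)


# ---------------------------------------------------------------------------
# status-conditional blood-pressure models (summary values, mmHg)

def _bp_models(cat: str, z: np.ndarray, p: GeneratorParams):
    """(mean, sd, lo, hi) for SBP and DBP given category and liability.

    The quadratic curvature acts on ``max(z, 0)``: frail subjects (high z)
    are pulled toward the low-BP extreme when their status puts them on the
    low-BP side (non-hypertensive, controlled) and toward the high-BP
    extreme otherwise, so both BP tails are frailty-enriched (the planted
    U-shape).  Robust subjects stay near the status-typical centre.
    """
    g, gd = p.sbp_curvature, p.dbp_curvature
    z2 = np.maximum(z, 0.0) ** 2
    c = np.full_like
    if cat == CAT_NON:
        return (125.0 - g * z2, 8.0, 85.0, 139.9), (74.0 - gd * z2, 7.0, 50.0, 89.9)
    if cat == CAT_UNT_S:
        return (150.0 + g * z2, 10.0, 140.0, 220.0), (c(z, 78.0), 8.0, 50.0, 89.9)
    if cat == CAT_UNT_D:
        return (c(z, 145.0), 12.0, 100.0, 210.0), (92.0 + gd * z2, 4.0, 90.0, 120.0)
    if cat == CAT_CTL:
        return (131.0 + 0.8 * z - 1.5 * z2, 10.0, 90.0, 149.9), \
               (74.5 - 0.8 * z - 1.5 * z2, 8.0, 50.0, 89.9)
    if cat == CAT_UNC_S:
        return (158.0 + g * z2, 9.0, 150.0, 230.0), (c(z, 78.0), 8.0, 50.0, 89.9)
    if cat == CAT_UNC_D:
        return (c(z, 140.0), 8.0, 100.0, 149.9), (93.0 + gd * z2, 4.0, 90.0, 125.0)
    if cat == CAT_UNC_B:
        return (162.0 + g * z2, 10.0, 150.0, 230.0), (95.0 + gd * z2, 5.0, 90.0, 125.0)
    raise ValueError(cat)


def _category_probs(z: np.ndarray, p: GeneratorParams) -> dict:
    """P(category | z) for every status category."""
    ph = expit(p.htn_logit0 + p.htn_logit_slope * z)
    pt = expit(p.treat_logit0 + p.treat_logit_slope * z)
    pc = expit(p.control_logit0 - p.control_logit_slope * z)
    fd = p.untreated_dbp_fraction
    s_only, d_only, both = p.uncontrolled_split
    unc = ph * pt * (1.0 - pc)
    return {
        CAT_NON: 1.0 - ph,
        CAT_UNT_S: ph * (1.0 - pt) * (1.0 - fd),
        CAT_UNT_D: ph * (1.0 - pt) * fd,
        CAT_CTL: ph * pt * pc,
        CAT_UNC_S: unc * s_only,
        CAT_UNC_D: unc * d_only,
        CAT_UNC_B: unc * both,
    }


# deficit bands of the two BP items (codebook v1): score in half-units per
# segment between the cuts — below first cut 0.5, reference band 0,
# then 0.5, then 1.
_SBP_CUTS = (100.0, 140.0, 160.0)
_DBP_CUTS = (60.0, 90.0, 100.0)
_SEG_HALF_SCORES = (1, 0, 1, 2)


def _band_score_pmf(mean, sd, lo, hi, cuts):
    """pmf over half-unit scores {0,1,2} of a truncated-normal BP value."""
    mean = np.asarray(mean, dtype=float)
    edges = [lo, *cuts, hi]
    denom = norm.cdf((hi - mean) / sd) - norm.cdf((lo - mean) / sd)
    denom = np.where(denom <= 0, np.nan, denom)
    pmf = [np.zeros_like(mean) for _ in range(3)]
    for (a, b), t in zip(zip(edges[:-1], edges[1:]), _SEG_HALF_SCORES):
        a_, b_ = max(a, lo), min(b, hi)
        if a_ >= b_:
            continue
        seg = (norm.cdf((b_ - mean) / sd) - norm.cdf((a_ - mean) / sd)) / denom
        pmf[t] = pmf[t] + np.clip(seg, 0.0, 1.0)
    total = pmf[0] + pmf[1] + pmf[2]
    return [np.nan_to_num(q / total) for q in pmf]


# ---------------------------------------------------------------------------
# quadrature oracle

@dataclass
class ExpectedCascade:
    """Analytic class fractions and class-wise cascade rates (probabilities)."""

    class_fractions: dict
    prevalence: dict        # P(HTN | class)
    treatment: dict         # P(treated | HTN, class)
    control: dict           # P(controlled | treated, class)


def expected_cascade(params: GeneratorParams, z_points: int = 1201,
                     include_bp_items: bool = True) -> ExpectedCascade:
    """Expected class-wise cascade rates by numerical integration over the
    liability distribution, conditioning on the BP status category so the
    two BP deficit items' contribution to the frailty class is exact.

    With ``include_bp_items=False`` the frailty class is computed from the
    40 pooled deficit items only (a deficit-only FI over 40 items; the
    0.10/0.21 cutoffs translate to the same half-score thresholds).  This
    removes the structural coupling between the BP deficit items and the
    cascade status, so that e.g. a zero deficit slope makes class and
    cascade exactly independent.
    """
    z = np.linspace(-6.0, 6.0, z_points)
    w = norm.pdf(z)
    w /= w.sum()
    p_def = expit(params.deficit_intercept + params.deficit_slope * z)

    # P(pooled deficit half-count 2j <= t) for the thresholds we need
    def cdf_at(k):  # k = max number of full deficits
        return binom.cdf(k, N_POOLED_ITEMS, p_def) if k >= 0 else np.zeros_like(p_def)

    cat_probs = _category_probs(z, params)
    denom = np.zeros(3)
    htn = np.zeros(3)
    treated = np.zeros(3)
    controlled = np.zeros(3)
    point_mass = [np.ones_like(z), np.zeros_like(z), np.zeros_like(z)]
    for cat in CATEGORIES:
        if include_bp_items:
            (sm, ss, slo, shi), (dm, ds, dlo, dhi) = _bp_models(cat, z, params)
            qs = _band_score_pmf(sm, ss, slo, shi, _SBP_CUTS)
            qd = _band_score_pmf(dm, ds, dlo, dhi, _DBP_CUTS)
        else:
            qs = qd = point_mass
        p_rob = np.zeros_like(z)
        p_rob_pre = np.zeros_like(z)
        for ts in range(3):
            for td in range(3):
                q = qs[ts] * qd[td]
                p_rob += q * cdf_at((_T_ROBUST - ts - td) // 2)
                p_rob_pre += q * cdf_at((_T_PREFRAIL - ts - td) // 2)
        masses = np.stack([p_rob, p_rob_pre - p_rob, 1.0 - p_rob_pre])
        contrib = (masses * (w * cat_probs[cat])).sum(axis=1)
        denom += contrib
        if cat in HTN_CATS:
            htn += contrib
        if cat in TREATED_CATS:
            treated += contrib
        if cat == CAT_CTL:
            controlled += contrib

    def as_dict(v):
        return dict(zip(CLASSES, v))

    return ExpectedCascade(
        class_fractions=as_dict(denom / denom.sum()),
        prevalence=as_dict(htn / denom),
        treatment=as_dict(treated / htn),
        control=as_dict(controlled / treated),
    )


# ---------------------------------------------------------------------------
# cohort generation

# uniform draw ranges for continuous laboratory items: (healthy, deficit),
# matched to the v1 codebook's score-0 and score-1 bands
_LAB_DRAWS = {
    "hemoglobin": ((12.2, 17.0), (7.8, 9.9)),
    "creatinine": ((0.55, 1.15), (1.75, 3.0)),
    "total_cholesterol": ((140.0, 235.0), (282.0, 360.0)),
    "triglyceride": ((55.0, 195.0), (405.0, 650.0)),
    "hdl_cholesterol": ((40.5, 75.0), (19.0, 29.5)),
    "fasting_glucose": ((74.0, 99.0), (127.0, 230.0)),
    "bun": ((8.0, 19.5), (31.0, 55.0)),
    "vitamin_d": ((20.5, 45.0), (4.0, 9.5)),
}
_RECORD_LABS = {"hemoglobin", "creatinine", "total_cholesterol", "triglyceride",
                "hdl_cholesterol", "fasting_glucose"}


def _tn(rng, mean, sd, lo, hi, size=None):
    mean = np.asarray(mean, dtype=float)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd,
                         size=size if size is not None else mean.shape,
                         random_state=rng)


def generate_cohort(params: GeneratorParams, codebook: DeficitCodebook = None):
    """Draw a cohort of :class:`ParticipantRecord` plus a ground-truth table.

    Returns ``(records, truth)`` where ``truth`` is a pandas DataFrame with
    the latent liability, status category and planted cascade states per
    subject.  Byte-identical for identical seed and parameters.
    """
    if params.n <= 0:
        raise ValueError("cohort size must be positive")
    if params.n_missing_bp + params.n_missing_questionnaire > params.n:
        raise ValueError("planted missingness exceeds cohort size")
    if codebook is None:
        codebook = default_codebook()

    rng = np.random.default_rng(params.seed)
    n = params.n
    z = rng.standard_normal(n)

    age = np.floor(_tn(rng, params.age_mean + params.age_z_slope * z,
                       params.age_sd, params.age_min, 105.0)).astype(int)
    male = rng.random(n) < expit(params.male_logit0 + params.male_logit_slope * z)

    # cascade status
    cat_p = _category_probs(z, params)
    cum = np.cumsum(np.stack([cat_p[c] for c in CATEGORIES]), axis=0)
    u = rng.random(n)
    cat_idx = (u[None, :] >= cum).sum(axis=0)
    cats = np.array(CATEGORIES, dtype=object)[cat_idx]

    # summary blood pressure, status-consistent (DBP first, SBP floored above it)
    sbp = np.empty(n)
    dbp = np.empty(n)
    for ci, cat in enumerate(CATEGORIES):
        m = cat_idx == ci
        if not m.any():
            continue
        (sm, ss, slo, shi), (dm, ds, dlo, dhi) = _bp_models(cat, z[m], params)
        dbp[m] = _tn(rng, dm, ds, dlo, dhi)
        lo = np.maximum(slo, dbp[m] + 5.0)
        sbp[m] = _tn(rng, sm, ss, np.minimum(lo, shi - 1.0), shi)

    is_htn = np.isin(cats, list(HTN_CATS))
    is_treated = np.isin(cats, list(TREATED_CATS))
    is_controlled = cats == CAT_CTL

    days = np.where(is_treated, rng.integers(20, 32, size=n), 0)
    on_med = is_treated.copy()

    # the three readings: 2 and 3 symmetric about the summary, 1 independent
    w_s = rng.normal(0.0, params.within_pair_noise_sd, size=n)
    w_d = rng.normal(0.0, params.within_pair_noise_sd, size=n)
    r1_s = sbp + rng.normal(0.0, params.reading1_noise_sd, size=n)
    r1_d = dbp + rng.normal(0.0, params.reading1_noise_sd, size=n)
    readings = np.stack([
        np.stack([r1_s, r1_d]),
        np.stack([sbp + w_s, dbp + w_d]),
        np.stack([sbp - w_s, dbp - w_d]),
    ])  # (reading, component, subject)
    # keep each reading physiologic: dbp at least 5 below sbp, above 30
    readings[:, 1, :] = np.clip(readings[:, 1, :],
                                31.0, readings[:, 0, :] - 5.0)

    # pooled deficits: one Bernoulli per non-BP codebook item
    pooled_rules = [r for r in codebook.items if r.key not in ("sbp", "dbp")]
    assert len(pooled_rules) == N_POOLED_ITEMS
    p_def = expit(params.deficit_intercept + params.deficit_slope * z)
    deficits = rng.random((n, N_POOLED_ITEMS)) < p_def[:, None]
    col = {r.key: j for j, r in enumerate(pooled_rules)}

    def lab_draw(key, d):
        healthy, sick = _LAB_DRAWS[key]
        lo = np.where(d, sick[0], healthy[0])
        hi = np.where(d, sick[1], healthy[1])
        return rng.uniform(lo, hi)

    labs = {k: lab_draw(k, deficits[:, col[k]]) for k in _LAB_DRAWS}

    bmi_def = deficits[:, col["obesity"]]
    bmi = np.where(bmi_def, rng.uniform(25.05, 33.0, n), rng.uniform(18.5, 24.9, n))
    height = np.where(male, _tn(rng, np.full(n, 1.67), 0.055, 1.45, 1.90),
                      _tn(rng, np.full(n, 1.54), 0.05, 1.35, 1.80))
    weight = bmi * height ** 2
    waist = 2.2 * bmi + 30.0 + rng.normal(0.0, 3.0, n)

    smoker = deficits[:, col["current_smoking"]]
    ever_packs = smoker | (rng.random(n) < 0.15)
    dm_dx = deficits[:, col["diabetes_dx"]]
    dm_med = dm_dx & (rng.random(n) < 0.7)
    lipid_med = deficits[:, col["dyslipidemia_dx"]] & (rng.random(n) < 0.5)

    # activity questionnaire, coherent with the inactivity deficit item
    exerciser = (~deficits[:, col["inactivity"]]) & (rng.random(n) < 0.8)
    pattern = rng.integers(0, 3, size=n)  # 0 vigorous, 1 moderate, 2 walking
    vig_s = np.where(exerciser & (pattern == 0), rng.integers(3, 7, n),
                     rng.integers(0, 3, n))
    vig_m = np.where(exerciser & (pattern == 0), rng.uniform(20, 60, n),
                     rng.uniform(5, 19, n))
    mod_s = np.where(exerciser & (pattern == 1), rng.integers(5, 8, n),
                     rng.integers(0, 5, n))
    mod_m = np.where(exerciser & (pattern == 1), rng.uniform(30, 60, n),
                     rng.uniform(5, 29, n))
    walk_s = np.where(exerciser & (pattern == 2), rng.integers(5, 8, n),
                      rng.integers(0, 5, n))
    walk_m = np.where(exerciser & (pattern == 2), rng.uniform(30, 60, n),
                      rng.uniform(5, 29, n))

    sodium = _tn(rng, 4.1 - 0.35 * z, 2.8, 0.2, 15.0)
    income = np.exp(rng.normal(np.log(1300.0) - 0.25 * z, 0.6))
    edu_latent = -0.6 * z + rng.standard_normal(n)
    education = 1 + (edu_latent[:, None] >= np.array([-0.3, 0.4, 1.1])).sum(axis=1)

    # planted missingness (exclusion fixture): disjoint random subjects
    miss_idx = rng.choice(n, size=params.n_missing_bp + params.n_missing_questionnaire,
                          replace=False)
    miss_bp = np.zeros(n, bool)
    miss_bp[miss_idx[:params.n_missing_bp]] = True
    miss_q = np.zeros(n, bool)
    miss_q[miss_idx[params.n_missing_bp:]] = True

    def response_value(rule, d):
        if rule.rule_kind == "binary":
            return "yes" if d else "no"
        if rule.rule_kind == "ordinal_map":
            mapping = rule.parameters["map"]
            hi = max(mapping, key=lambda k: mapping[k])
            lo = min(mapping, key=lambda k: mapping[k])
            return hi if d else lo
        raise AssertionError(rule.key)

    records = []
    truth_rows = []
    for i in range(n):
        items = {}
        for rule in pooled_rules:
            if rule.source_field != "response":
                continue
            d = bool(deficits[i, col[rule.key]])
            if rule.key in _LAB_DRAWS:  # numeric response items (BUN, vitamin D)
                items[rule.key] = f"{labs[rule.key][i]:.2f}"
            else:
                items[rule.key] = response_value(rule, d)

        if miss_bp[i]:
            bp = [BPReading(float(readings[0, 0, i]), float(readings[0, 1, i])),
                  BPReading(None, None),
                  BPReading(float(readings[2, 0, i]), float(readings[2, 1, i]))]
        else:
            bp = [BPReading(float(readings[j, 0, i]), float(readings[j, 1, i]))
                  for j in range(3)]

        records.append(ParticipantRecord(
            id=f"S{i + 1:06d}",
            age=int(age[i]),
            sex="male" if male[i] else "female",
            bp_readings=bp,
            antihypertensive_days_per_month=None if miss_q[i] else int(days[i]),
            on_antihypertensive_med=None if miss_q[i] else bool(on_med[i]),
            height=round(float(height[i]), 3),
            weight=round(float(weight[i]), 2),
            waist=round(float(waist[i]), 1),
            creatinine=round(float(labs["creatinine"][i]), 3),
            fasting_glucose=round(float(labs["fasting_glucose"][i]), 1),
            total_cholesterol=round(float(labs["total_cholesterol"][i]), 1),
            triglyceride=round(float(labs["triglyceride"][i]), 1),
            hdl_cholesterol=round(float(labs["hdl_cholesterol"][i]), 1),
            hemoglobin=round(float(labs["hemoglobin"][i]), 2),
            sodium_intake=round(float(sodium[i]), 2),
            income_month_usd=round(float(income[i]), 0),
            education_level=int(education[i]),
            smoker_current=bool(smoker[i]),
            lifetime_packs_ge_5=bool(ever_packs[i]),
            on_lipid_med=bool(lipid_med[i]),
            on_glucose_med_or_insulin=bool(dm_med[i]),
            physician_dx_diabetes=bool(dm_dx[i]),
            vigorous_sessions_per_week=int(vig_s[i]),
            vigorous_minutes=round(float(vig_m[i]), 1),
            moderate_sessions_per_week=int(mod_s[i]),
            moderate_minutes=round(float(mod_m[i]), 1),
            walking_sessions_per_week=int(walk_s[i]),
            walking_minutes=round(float(walk_m[i]), 1),
            item_responses=items,
        ))
        truth_rows.append({
            "id": records[-1].id,
            "z": float(z[i]),
            "category": cats[i],
            "htn": bool(is_htn[i]),
            "treated": bool(is_treated[i]),
            "controlled": bool(is_controlled[i]),
            "sbp_summary": float(sbp[i]),
            "dbp_summary": float(dbp[i]),
            "missing_bp": bool(miss_bp[i]),
            "missing_questionnaire": bool(miss_q[i]),
        })
    return records, pd.DataFrame(truth_rows)


def params_to_dict(params: GeneratorParams) -> dict:
    d = dataclasses.asdict(params)
    d["uncontrolled_split"] = list(d["uncontrolled_split"])
    return d


def params_from_dict(d: dict) -> GeneratorParams:
    d = dict(d)
    if "uncontrolled_split" in d:
        d["uncontrolled_split"] = tuple(d["uncontrolled_split"])
    return GeneratorParams(**d)
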