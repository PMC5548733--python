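import pytest

from frailcascade.cohort import BPReading, ParticipantRecord, RunConfig
from frailcascade.frailty import default_codebook


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture()
def config():
    return RunConfig()


def _healthy_response(rule):
    """A raw response scoring 0 under the given codebook rule."""
    if rule.rule_kind == "binary":
        return "no"
    if rule.rule_kind == "ordinal_map":
        mapping = rule.parameters["map"]
        return min(mapping, key=lambda k: mapping[k])
    # threshold_cut: centre of the score-0 band
    for lo, hi, score in rule.parameters["bands"]:
        if score == 0:
            if lo is None:
                return str(hi - 6.0)
            if hi is None:
                return str(lo + 10.0)
            return str((lo + hi) / 2.0)
    raise AssertionError(rule.key)


@pytest.fixture(scope="session")
def make_record(codebook):
    """Factory for a fully healthy participant; overrides plant deficits."""

    def _make(record_overrides=None, item_overrides=None):
        items = {r.key: _healthy_response(r) for r in codebook.items
                 if r.source_field == "response"}
        if item_overrides:
            items.update(item_overrides)
        kwargs = dict(
            id="T000001", age=70, sex="male",
            bp_readings=[BPReading(120.0, 70.0)] * 3,
            antihypertensive_days_per_month=0,
            on_antihypertensive_med=False,
            height=1.65, weight=60.0, waist=80.0,
            creatinine=0.9, fasting_glucose=90.0,
            total_cholesterol=180.0, triglyceride=120.0,
            hdl_cholesterol=55.0, hemoglobin=14.0,
            sodium_intake=4.0, income_month_usd=1500.0, education_level=3,
            smoker_current=False, lifetime_packs_ge_5=False,
            on_lipid_med=False, on_glucose_med_or_insulin=False,
            physician_dx_diabetes=False,
            vigorous_sessions_per_week=0, vigorous_minutes=0.0,
            moderate_sessions_per_week=5, moderate_minutes=40.0,
            walking_sessions_per_week=2, walking_minutes=20.0,
        )
        if record_overrides:
            kwargs.update(record_overrides)
        return ParticipantRecord(item_responses=items, **kwargs)

    return _make
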