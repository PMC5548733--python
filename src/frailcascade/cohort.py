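"""Cohort data model, CSV round-trip, run configuration, and exclusion filter.

The cohort file is a plain CSV (schema ``v1``) with one row per participant:
demographics, three seated blood-pressure readings, antihypertensive
medication use, fasting labs, activity questionnaire, and 42 health-deficit
item responses (columns prefixed ``item_``).  Missing values are empty cells.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

SCHEMA_VERSION = "1"
SCHEMA_COMMENT = "# frailcascade cohort schema v1"

ITEM_PREFIX = "item_"

#: exclusion reason codes, in precedence order
REASON_MISSING_BP = "missing_bp"
REASON_MISSING_QUESTIONNAIRE = "missing_htn_questionnaire"


class SchemaError(ValueError):
    """Raised when a cohort file's header does not match the declared schema."""


@dataclass(frozen=True)
class BPReading:
    """One sphygmomanometer reading (systolic/diastolic, mmHg)."""

    sbp: Optional[float]
    dbp: Optional[float]

    @property
    def is_missing(self) -> bool:
        return self.sbp is None or self.dbp is None


@dataclass
class ParticipantRecord:
    """One elderly subject's raw survey measurements and deficit-item responses."""

    id: str
    age: int
    sex: str  # "male" | "female"
    bp_readings: list  # exactly 3 BPReading
    antihypertensive_days_per_month: Optional[int] = None
    on_antihypertensive_med: Optional[bool] = None
    height: Optional[float] = None  # m
    weight: Optional[float] = None  # kg
    waist: Optional[float] = None  # cm
    creatinine: Optional[float] = None  # mg/dL
    fasting_glucose: Optional[float] = None  # mg/dL
    total_cholesterol: Optional[float] = None  # mg/dL
    triglyceride: Optional[float] = None  # mg/dL
    hdl_cholesterol: Optional[float] = None  # mg/dL
    hemoglobin: Optional[float] = None  # g/dL
    sodium_intake: Optional[float] = None  # g/day
    income_month_usd: Optional[float] = None
    education_level: Optional[int] = None  # 1=elementary or lower .. 4=college+
    smoker_current: Optional[bool] = None
    lifetime_packs_ge_5: Optional[bool] = None
    on_lipid_med: Optional[bool] = None
    on_glucose_med_or_insulin: Optional[bool] = None
    physician_dx_diabetes: Optional[bool] = None
    vigorous_sessions_per_week: Optional[int] = None
    vigorous_minutes: Optional[float] = None
    moderate_sessions_per_week: Optional[int] = None
    moderate_minutes: Optional[float] = None
    walking_sessions_per_week: Optional[int] = None
    walking_minutes: Optional[float] = None
    item_responses: dict = field(default_factory=dict)

    @property
    def has_missing_bp(self) -> bool:
        return len(self.bp_readings) != 3 or any(r.is_missing for r in self.bp_readings)

    @property
    def has_missing_htn_questionnaire(self) -> bool:
        return self.on_antihypertensive_med is None


@dataclass
class RunConfig:
    """All analysis thresholds in one editable place.

    Defaults follow standard elderly-hypertension conventions: HTN at
    140/90 mmHg or on medication, control target 150/90 mmHg, treatment at
    >= 20 medication-days per month, frailty-index cutoffs 0.10/0.21 with an
    80% item-completeness floor.
    """

    htn_sbp_threshold: float = 140.0
    htn_dbp_threshold: float = 90.0
    control_sbp: float = 150.0
    control_dbp: float = 90.0
    treatment_days_min: int = 20
    fi_robust_max: float = 0.10
    fi_prefrail_max: float = 0.21
    fi_min_items_fraction: float = 0.80
    prehtn_semantics: str = "as_printed_and"  # or "jnc7_or"
    sbp_bin_width: float = 10.0
    dbp_bin_width: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fi_robust_max < self.fi_prefrail_max < 1):
            raise ValueError("require 0 < fi_robust_max < fi_prefrail_max < 1")
        for name in ("htn_sbp_threshold", "htn_dbp_threshold", "control_sbp",
                     "control_dbp", "sbp_bin_width", "dbp_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.prehtn_semantics not in ("as_printed_and", "jnc7_or"):
            raise ValueError(f"unknown prehtn_semantics {self.prehtn_semantics!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# CSV schema

_SCALAR_COLUMNS = [
    ("id", str),
    ("age", int),
    ("sex", str),
    ("sbp1", float), ("dbp1", float),
    ("sbp2", float), ("dbp2", float),
    ("sbp3", float), ("dbp3", float),
    ("antihypertensive_days_per_month", int),
    ("on_antihypertensive_med", bool),
    ("height", float), ("weight", float), ("waist", float),
    ("creatinine", float), ("fasting_glucose", float),
    ("total_cholesterol", float), ("triglyceride", float),
    ("hdl_cholesterol", float), ("hemoglobin", float),
    ("sodium_intake", float), ("income_month_usd", float),
    ("education_level", int),
    ("smoker_current", bool), ("lifetime_packs_ge_5", bool),
    ("on_lipid_med", bool), ("on_glucose_med_or_insulin", bool),
    ("physician_dx_diabetes", bool),
    ("vigorous_sessions_per_week", int), ("vigorous_minutes", float),
    ("moderate_sessions_per_week", int), ("moderate_minutes", float),
    ("walking_sessions_per_week", int), ("walking_minutes", float),
]

_BOOL_TRUE = {"true", "1", "yes"}
_BOOL_FALSE = {"false", "0", "no"}


def _is_na(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


def _parse_cell(value, kind):
    if _is_na(value):
        return None
    if kind is bool:
        s = str(value).strip().lower()
        if s in _BOOL_TRUE:
            return True
        if s in _BOOL_FALSE:
            return False
        raise ValueError(f"not a boolean: {value!r}")
    if kind is int:
        return int(round(float(value)))
    if kind is float:
        return float(value)
    return str(value)


def _format_cell(value):
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)
    return str(value)


def validate_record(rec: ParticipantRecord, item_keys=None) -> list:
    """Return the list of invariant violations for one record (empty if valid).

    Missing BP readings or questionnaire fields are *not* violations — they
    are handled by :func:`apply_exclusions` downstream.
    """
    reasons = []
    if len(rec.bp_readings) != 3:
        reasons.append("bp_readings count != 3")
    else:
        for i, r in enumerate(rec.bp_readings, start=1):
            if r.is_missing:
                continue
            if not (r.sbp > r.dbp > 0):
                reasons.append(f"reading {i}: require sbp > dbp > 0")
    if rec.age is None or rec.age < 65:
        reasons.append("age < 65")
    if rec.sex not in ("male", "female"):
        reasons.append(f"sex not in {{male, female}}: {rec.sex!r}")
    d = rec.antihypertensive_days_per_month
    if d is not None and not (0 <= d <= 31):
        reasons.append("antihypertensive_days_per_month outside 0-31")
    if item_keys is not None:
        extra = set(rec.item_responses) - set(item_keys)
        if extra:
            reasons.append(f"unknown item keys: {sorted(extra)}")
    return reasons


def write_cohort(records, path) -> None:
    """Serialize records to the v1 cohort CSV (missing values as empty cells)."""
    item_keys = sorted({k for r in records for k in r.item_responses})
    header = [c for c, _ in _SCALAR_COLUMNS] + [ITEM_PREFIX + k for k in item_keys]
    lines = [SCHEMA_COMMENT, ",".join(header)]
    for rec in records:
        row = []
        for col, _kind in _SCALAR_COLUMNS:
            if col.startswith(("sbp", "dbp")) and col[-1].isdigit():
                idx = int(col[-1]) - 1
                reading = rec.bp_readings[idx] if idx < len(rec.bp_readings) else BPReading(None, None)
                row.append(_format_cell(getattr(reading, col[:3])))
            else:
                row.append(_format_cell(getattr(rec, col)))
        for k in item_keys:
            row.append(_format_cell(rec.item_responses.get(k)))
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cohort(path, codebook=None):
    """Read a v1 cohort CSV.

    Returns ``(records, rejected)`` where ``rejected`` is a list of
    ``(row_index, id, [reasons])`` for rows violating record invariants —
    rejected rows are reported, never silently dropped.

    Raises :class:`SchemaError` if a mandatory column is absent.
    """
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    mandatory = [c for c, _ in _SCALAR_COLUMNS]
    missing_cols = [c for c in mandatory if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {missing_cols}")
    item_cols = [c for c in df.columns if c.startswith(ITEM_PREFIX)]
    item_keys = [c[len(ITEM_PREFIX):] for c in item_cols]
    codebook_keys = None
    if codebook is not None:
        codebook_keys = [rule.key for rule in codebook.items]
        unknown = set(item_keys) - set(codebook_keys)
        if unknown:
            raise SchemaError(f"item columns not in codebook: {sorted(unknown)}")

    records, rejected = [], []
    for i, raw in enumerate(df.to_dict("records")):
        try:
            readings = [
                BPReading(_parse_cell(raw[f"sbp{j}"], float), _parse_cell(raw[f"dbp{j}"], float))
                for j in (1, 2, 3)
            ]
            kwargs = {}
            for col, kind in _SCALAR_COLUMNS:
                if col.startswith(("sbp", "dbp")) and col[-1].isdigit():
                    continue
                kwargs[col] = _parse_cell(raw[col], kind)
            items = {}
            for col, key in zip(item_cols, item_keys):
                v = raw[col]
                if not _is_na(v):
                    items[key] = v
            rec = ParticipantRecord(bp_readings=readings, item_responses=items, **kwargs)
        except (ValueError, TypeError) as exc:
            rejected.append((i, raw.get("id", "?"), [f"parse error: {exc}"]))
            continue
        reasons = validate_record(rec, item_keys=codebook_keys)
        if reasons:
            rejected.append((i, rec.id, reasons))
        else:
            records.append(rec)
    return records, rejected


@dataclass
class ExclusionResult:
    kept: list
    excluded: list  # (ParticipantRecord, reason-code)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def counts(self) -> dict:
        out = {REASON_MISSING_BP: 0, REASON_MISSING_QUESTIONNAIRE: 0}
        for _, reason in self.excluded:
            out[reason] += 1
        return out


def apply_exclusions(records) -> ExclusionResult:
    """Partition records into analysable and excluded sets.

    A record is excluded iff any of its three BP readings is missing, or the
    hypertension medication questionnaire is unanswered.  When both apply,
    the missing-BP reason takes precedence.  Idempotent: kept records are
    never excluded on a second pass.
    """
    kept, excluded = [], []
    for rec in records:
        if rec.has_missing_bp:
            excluded.append((rec, REASON_MISSING_BP))
        elif rec.has_missing_htn_questionnaire:
            excluded.append((rec, REASON_MISSING_QUESTIONNAIRE))
        else:
            kept.append(rec)
    return ExclusionResult(kept=kept, excluded=excluded)
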