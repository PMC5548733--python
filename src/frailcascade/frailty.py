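"""Cumulative-deficit frailty index over a 42-item codebook.

The frailty index (FI) is the ratio of health deficits present to deficits
assessed, a continuous score from total fitness (0) to total frailty (1).
Items span five groups — 11 comorbidities, 8 functional abilities, 8 signs
and symptoms, 13 laboratory values (including the summarized blood
pressure), and 2 lifestyle factors (current smoking and obesity).  Subjects
are classified robust (FI <= 0.10), pre-frail (0.10 < FI <= 0.21) or frail
(FI > 0.21).

Per-item coding rules are *data*, not code: the shipped TSV codebook maps
each item to a score in [0, 1] via a binary, ordinal, or threshold-band
rule; continuous laboratory items use 0 / 0.5 / 1 bands at clinical
reference limits, and obesity uses the Asian-Pacific BMI >= 25 cutoff.
Missing raw responses score as missing, never 0; the FI denominator is the
number of items actually assessed, subject to an 80% completeness floor
(34 of 42 items).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .clinical import BPSummary, ComorbidityProfile
from .cohort import ParticipantRecord, RunConfig

ROBUST = "robust"
PRE_FRAIL = "pre_frail"
FRAIL = "frail"

EXPECTED_CATEGORY_COUNTS = {
    "comorbidity": 11,
    "functional": 8,
    "sign_symptom": 8,
    "laboratory": 13,
    "lifestyle": 2,
}

_BINARY_TRUE = {True, 1, "1", "yes", "true"}
_BINARY_FALSE = {False, 0, "0", "no", "false"}


class CodebookError(ValueError):
    """Raised for malformed codebooks or rules referencing absent fields."""


@dataclass(frozen=True)
class ItemRule:
    key: str
    category: str
    rule_kind: str  # binary | ordinal_map | threshold_cut
    parameters: dict
    source_field: str  # "response", "record.<field>", "bp.<field>", "profile.<field>"

    def score(self, raw) -> Optional[float]:
        """Score one raw value in [0, 1]; ``None`` stays missing."""
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return None
        if self.rule_kind == "binary":
            v = raw.strip().lower() if isinstance(raw, str) else raw
            if v in _BINARY_TRUE:
                return 1.0
            if v in _BINARY_FALSE:
                return 0.0
            raise CodebookError(f"item {self.key!r}: not a binary response: {raw!r}")
        if self.rule_kind == "ordinal_map":
            mapping = self.parameters["map"]
            key = raw.strip().lower() if isinstance(raw, str) else raw
            if key not in mapping:
                raise CodebookError(
                    f"item {self.key!r}: response {raw!r} not in ordinal map "
                    f"{sorted(mapping)}")
            return float(mapping[key])
        if self.rule_kind == "threshold_cut":
            x = float(raw)
            for lo, hi, score in self.parameters["bands"]:
                if (lo is None or x >= lo) and (hi is None or x < hi):
                    return float(score)
            raise CodebookError(f"item {self.key!r}: value {x} falls in no band")
        raise CodebookError(f"item {self.key!r}: unknown rule kind {self.rule_kind!r}")


@dataclass
class DeficitCodebook:
    items: list  # of ItemRule, ordered

    def __post_init__(self):
        if len(self.items) != 42:
            raise CodebookError(f"codebook must define exactly 42 items, "
                                f"got {len(self.items)}")
        counts = {}
        for rule in self.items:
            counts[rule.category] = counts.get(rule.category, 0) + 1
        if counts != EXPECTED_CATEGORY_COUNTS:
            raise CodebookError(f"category counts {counts} != "
                                f"{EXPECTED_CATEGORY_COUNTS}")
        for rule in self.items:
            for s in _rule_output_scores(rule):
                if not 0.0 <= s <= 1.0:
                    raise CodebookError(f"item {rule.key!r}: score {s} outside [0, 1]")

    @property
    def keys(self) -> list:
        return [rule.key for rule in self.items]

    def __len__(self) -> int:
        return len(self.items)


def _rule_output_scores(rule: ItemRule):
    if rule.rule_kind == "binary":
        return [0.0, 1.0]
    if rule.rule_kind == "ordinal_map":
        return [float(v) for v in rule.parameters["map"].values()]
    if rule.rule_kind == "threshold_cut":
        return [float(b[2]) for b in rule.parameters["bands"]]
    raise CodebookError(f"unknown rule kind {rule.rule_kind!r}")


def load_codebook(path) -> DeficitCodebook:
    """Parse a tab-separated codebook (columns: item_key, category,
    rule_kind, parameters as JSON, source_field)."""
    rules = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["item_key", "category", "rule_kind", "parameters", "source_field"]
        if header != expected:
            raise CodebookError(f"codebook header {header} != {expected}")
        for line in fh:
            if not line.strip():
                continue
            key, category, kind, params, source = line.rstrip("\n").split("\t")
            rules.append(ItemRule(key=key, category=category, rule_kind=kind,
                                  parameters=json.loads(params),
                                  source_field=source))
    return DeficitCodebook(items=rules)


def default_codebook() -> DeficitCodebook:
    """The codebook shipped with the package (v1 reference coding)."""
    ref = resources.files("frailcascade") / "data" / "deficit_codebook_v1.tsv"
    with resources.as_file(ref) as path:
        return load_codebook(path)


@dataclass
class DerivedInputs:
    """Derived quantities some codebook rules read (summary BP, BMI...)."""

    bp: Optional[BPSummary] = None
    profile: Optional[ComorbidityProfile] = None


@dataclass
class FrailtyResult:
    fi: Optional[float]
    items_assessed: int
    deficit_sum: float
    frailty_class: Optional[str] = None
    per_item_scores: dict = field(default_factory=dict)

    @property
    def fi_defined(self) -> bool:
        return self.fi is not None


def _resolve_raw(rule: ItemRule, record: ParticipantRecord, derived: DerivedInputs):
    src = rule.source_field
    if src == "response":
        return record.item_responses.get(rule.key)
    obj_name, _, attr = src.partition(".")
    if obj_name == "record":
        base = record
    elif obj_name == "bp":
        base = derived.bp if derived is not None else None
    elif obj_name == "profile":
        base = derived.profile if derived is not None else None
    else:
        raise CodebookError(f"item {rule.key!r}: unknown source {src!r}")
    if base is None:
        return None
    if not hasattr(base, attr):
        raise CodebookError(f"item {rule.key!r}: source field {src!r} "
                            f"does not exist")
    return getattr(base, attr)


def code_deficits(record: ParticipantRecord, derived: DerivedInputs,
                  codebook: DeficitCodebook) -> dict:
    """Score every codebook item for one record; missing stays ``None``."""
    return {rule.key: rule.score(_resolve_raw(rule, record, derived))
            for rule in codebook.items}


def compute_fi(per_item_scores: dict,
               min_items_fraction: float = 0.80) -> FrailtyResult:
    """FI = sum(non-missing scores) / count(non-missing scores).

    Undefined (``fi=None``) when fewer than ``ceil(min_items_fraction * K)``
    of the K codebook items were assessed.
    """
    present = {k: v for k, v in per_item_scores.items() if v is not None}
    n = len(present)
    total = sum(present.values())
    floor = math.ceil(min_items_fraction * len(per_item_scores))
    fi = total / n if n >= floor and n > 0 else None
    return FrailtyResult(fi=fi, items_assessed=n, deficit_sum=total,
                         per_item_scores=dict(per_item_scores))


def classify_frailty(fi: float, config: RunConfig) -> str:
    """Robust for FI <= 0.10, pre-frail for 0.10 < FI <= 0.21, frail above."""
    if fi is None:
        raise ValueError("frailty index undefined (insufficient items)")
    if not 0.0 <= fi <= 1.0:
        raise ValueError(f"frailty index outside [0, 1]: {fi}")
    if fi <= config.fi_robust_max:
        return ROBUST
    if fi <= config.fi_prefrail_max:
        return PRE_FRAIL
    return FRAIL


def frailty_result(record: ParticipantRecord, derived: DerivedInputs,
                   codebook: DeficitCodebook, config: RunConfig) -> FrailtyResult:
    """Code deficits, compute the FI, and classify in one call."""
    result = compute_fi(code_deficits(record, derived, codebook),
                        config.fi_min_items_fraction)
    if result.fi is not None:
        result.frailty_class = classify_frailty(result.fi, config)
    return result
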