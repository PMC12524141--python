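"""Machine-readable rule-set parameterizing every quality dimension.

The rule-set encodes, per cancer type, the mandatory template fields, the
per-field value rules (type / allowed set / range / format), cross-link rules,
modality declaration columns, annotation label vocabularies, the
de-identification profile, deduplication thresholds, age-bin edges and the
fairness dominance share.  It loads from YAML or JSON and round-trips through
:meth:`QualityRuleSet.to_dict`.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any, Optional

import yaml

CANCER_TYPES = ("breast", "lung", "colorectal", "prostate")
FIELD_TYPES = ("integer", "real", "categorical", "date", "free-text")
LABEL_CLASSES = ("malignant", "benign", "other")


class RulesetError(Exception):
    """Schema violation while loading or validating a rule-set."""


@dataclass
class FieldRule:
    type: str = "free-text"
    allowed: Optional[list[str]] = None
    min: Optional[float] = None
    max: Optional[float] = None
    pattern: Optional[str] = None

    @property
    def constrained(self) -> bool:
        """A rule with no constraint carries nothing validity can assess."""
        if self.type in ("integer", "real", "date"):
            return True
        return bool(self.allowed) or self.pattern is not None

    def is_valid(self, value: Any) -> bool:
        s = str(value).strip()
        if self.type == "integer":
            try:
                v = int(s)
            except ValueError:
                return False
            return self._in_range(v)
        if self.type == "real":
            try:
                v = float(s)
            except ValueError:
                return False
            return self._in_range(v)
        if self.type == "date":
            for fmt in ("%Y-%m-%d", "%Y%m%d"):
                try:
                    from datetime import datetime
                    datetime.strptime(s, fmt)
                    return True
                except ValueError:
                    continue
            return False
        if self.allowed is not None and s not in self.allowed:
            return False
        if self.pattern is not None and not re.fullmatch(self.pattern, s):
            return False
        return True

    def _in_range(self, v: float) -> bool:
        if self.min is not None and v < self.min:
            return False
        if self.max is not None and v > self.max:
            return False
        return True


@dataclass
class CrosslinkRule:
    """condition on field A -> requirement on field B.

    ``requirement`` is one of ``missing``, ``nonmissing`` or ``equals``
    (with ``require_value``).  The rule is applicable for a patient when the
    condition field is non-missing.
    """

    name: str
    when_field: str
    when_equals: Optional[str] = None
    require_field: str = ""
    requirement: str = "missing"
    require_value: Optional[str] = None

    def applicable(self, record: dict) -> bool:
        return record.get(self.when_field) is not None

    def condition_holds(self, record: dict) -> bool:
        if self.when_equals is None:
            return True
        return str(record.get(self.when_field)) == self.when_equals

    def holds(self, record: dict) -> bool:
        if not self.condition_holds(record):
            return True
        v = record.get(self.require_field)
        if self.requirement == "missing":
            return v is None
        if self.requirement == "nonmissing":
            return v is not None
        if self.requirement == "equals":
            return v is not None and str(v) == self.require_value
        raise RulesetError(f"unknown crosslink requirement {self.requirement!r}")


@dataclass
class LabelEntry:
    code: int
    name: str
    klass: str = "other"  # malignant | benign | other


@dataclass
class DeidProfile:
    forbidden_tags: list[str] = field(default_factory=lambda: [
        "PatientSex", "PatientAge", "PatientName", "PatientBirthDate"])
    date_tags: list[str] = field(default_factory=lambda: ["StudyDate", "SeriesDate"])
    anchor_date: str = "2000-01-01"
    offset_modulus: int = 365

    def anchor(self) -> date:
        return date.fromisoformat(self.anchor_date)


@dataclass
class DedupConfig:
    high: float = 0.1
    normal: float = 10.0
    resample_size: int = 64
    slice_pair_cap: int = 200

    def threshold(self, grade: str) -> float:
        if grade == "high":
            return self.high
        if grade == "normal":
            return self.normal
        raise RulesetError(f"unknown similarity grade {grade!r}")


@dataclass
class QualityRuleSet:
    mandatory_fields: dict[str, list[str]] = field(default_factory=dict)
    field_rules: dict[str, FieldRule] = field(default_factory=dict)
    crosslink_rules: list[CrosslinkRule] = field(default_factory=list)
    #: timepoint ordinal -> template column carrying that timepoint's declaration
    modality_declaration_fields: dict[int, str] = field(default_factory=dict)
    #: (cancer type, modality) -> {code: LabelEntry}
    label_vocabulary: dict[tuple[str, str], dict[int, LabelEntry]] = field(
        default_factory=dict)
    deid_profile: DeidProfile = field(default_factory=DeidProfile)
    dedup: DedupConfig = field(default_factory=DedupConfig)
    age_bin_edges: list[int] = field(default_factory=lambda: list(range(20, 100, 5)))
    dominance_share: float = 0.8
    #: variables structurally single-class per cancer type (not flagged as dominance)
    structurally_fixed: dict[str, list[str]] = field(
        default_factory=lambda: {"prostate": ["sex"]})
    count_declared_absent: bool = True
    categorical_other_floor: float = 0.0

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mandatory_fields": copy.deepcopy(self.mandatory_fields),
            "field_rules": {
                name: {k: v for k, v in vars(rule).items() if v is not None}
                for name, rule in sorted(self.field_rules.items())
            },
            "crosslink_rules": [
                {k: v for k, v in vars(r).items() if v is not None}
                for r in self.crosslink_rules
            ],
            "modality_declaration_fields": {
                str(k): v for k, v in sorted(self.modality_declaration_fields.items())
            },
            "label_vocabulary": {
                f"{cancer}/{modality}": {
                    str(code): {"name": e.name, "class": e.klass}
                    for code, e in sorted(entries.items())
                }
                for (cancer, modality), entries in sorted(self.label_vocabulary.items())
            },
            "deid_profile": vars(self.deid_profile).copy(),
            "dedup": vars(self.dedup).copy(),
            "age_bin_edges": list(self.age_bin_edges),
            "dominance_share": self.dominance_share,
            "structurally_fixed": copy.deepcopy(self.structurally_fixed),
            "count_declared_absent": self.count_declared_absent,
            "categorical_other_floor": self.categorical_other_floor,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "QualityRuleSet":
        rs = cls()
        if "mandatory_fields" in raw:
            rs.mandatory_fields = {str(k): list(v)
                                   for k, v in raw["mandatory_fields"].items()}
        if "field_rules" in raw:
            rs.field_rules = {}
            for name, spec in raw["field_rules"].items():
                unknown = set(spec) - {"type", "allowed", "min", "max", "pattern"}
                if unknown:
                    raise RulesetError(
                        f"field_rules.{name}: unknown keys {sorted(unknown)}")
                rule = FieldRule(**spec)
                if rule.type not in FIELD_TYPES:
                    raise RulesetError(
                        f"field_rules.{name}.type: {rule.type!r} not in {FIELD_TYPES}")
                rs.field_rules[name] = rule
        if "crosslink_rules" in raw:
            rs.crosslink_rules = [CrosslinkRule(**r) for r in raw["crosslink_rules"]]
        if "modality_declaration_fields" in raw:
            rs.modality_declaration_fields = {
                int(k): str(v)
                for k, v in raw["modality_declaration_fields"].items()}
        if "label_vocabulary" in raw:
            rs.label_vocabulary = {}
            for key, entries in raw["label_vocabulary"].items():
                try:
                    cancer, modality = key.split("/")
                except ValueError as exc:
                    raise RulesetError(
                        f"label_vocabulary key {key!r} must be 'cancer/MODALITY'"
                    ) from exc
                rs.label_vocabulary[(cancer, modality)] = {
                    int(code): LabelEntry(code=int(code), name=e["name"],
                                          klass=e.get("class", "other"))
                    for code, e in entries.items()}
        if "deid_profile" in raw:
            rs.deid_profile = DeidProfile(**raw["deid_profile"])
        if "dedup" in raw:
            rs.dedup = DedupConfig(**raw["dedup"])
        for key in ("age_bin_edges", "dominance_share", "structurally_fixed",
                    "count_declared_absent", "categorical_other_floor"):
            if key in raw:
                setattr(rs, key, raw[key])
        return rs


# ---------------------------------------------------------------------------
# Shipped defaults

#: Mammography lesion categories (six-label vocabulary).
_MG_LABELS = {
    1: ("Benign", "benign"),
    2: ("Suspicious or Indeterminate", "other"),
    3: ("Malignant", "malignant"),
    4: ("Calcification", "other"),
    5: ("Surgical clip", "other"),
    6: ("Axial lymph node", "other"),
}
#: Three-label vocabulary used where no modality-specific list is configured.
_BASIC_LABELS = {
    1: ("Benign", "benign"),
    2: ("Suspicious or Indeterminate", "other"),
    3: ("Malignant", "malignant"),
}


def default_ruleset() -> QualityRuleSet:
    """The shipped default rule-set.

    Field rules and mandatory lists are representative template defaults;
    label vocabularies encode the breast MG six-label and breast MR
    three-label lists, with the generic three-label vocabulary elsewhere.
    """
    rs = QualityRuleSet()
    common_mandatory = ["sex", "age", "stage", "biopsy", "primary_diagnosis_text",
                        "modalities_t1"]
    rs.mandatory_fields = {c: list(common_mandatory) for c in CANCER_TYPES}
    rs.field_rules = {
        "sex": FieldRule(type="categorical", allowed=["M", "F"]),
        "age": FieldRule(type="integer", min=0, max=120),
        "grade": FieldRule(type="categorical", allowed=["1", "2", "3", "4", "5"]),
        "stage": FieldRule(type="categorical", allowed=["I", "II", "III", "IV"]),
        "histological_type": FieldRule(type="categorical", allowed=[
            "IDC", "ILC", "DCIS", "IMC", "Adenocarcinoma", "Squamous",
            "Small-cell", "Large-cell", "Other"]),
        "biopsy": FieldRule(type="categorical", allowed=["Biopsy", "No Biopsy"]),
        "er_status": FieldRule(type="categorical", allowed=["positive", "negative"]),
        "pr_status": FieldRule(type="categorical", allowed=["positive", "negative"]),
        "her2_status": FieldRule(type="categorical", allowed=["positive", "negative"]),
        "primary_diagnosis_text": FieldRule(type="free-text"),
        "modalities_t1": FieldRule(type="free-text"),
        "modalities_t2": FieldRule(type="free-text"),
    }
    rs.crosslink_rules = [
        CrosslinkRule(name="biomarkers_require_biopsy", when_field="biopsy",
                      when_equals="No Biopsy", require_field="her2_status",
                      requirement="missing"),
    ]
    rs.modality_declaration_fields = {1: "modalities_t1", 2: "modalities_t2",
                                      3: "modalities_t3"}
    vocab: dict[tuple[str, str], dict[int, LabelEntry]] = {}
    from .repo_model import MODALITY_CODES
    for cancer in CANCER_TYPES:
        for modality in MODALITY_CODES:
            src = _MG_LABELS if (cancer, modality) == ("breast", "MG") else _BASIC_LABELS
            vocab[(cancer, modality)] = {
                code: LabelEntry(code=code, name=name, klass=klass)
                for code, (name, klass) in src.items()}
    rs.label_vocabulary = vocab
    return rs


def load_ruleset(config_path: Path) -> QualityRuleSet:
    """Load a YAML/JSON rule-set file, merged over the shipped defaults."""
    path = Path(config_path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise RulesetError(f"{path}: rule-set must be a mapping")
    base = default_ruleset().to_dict()
    merged = {**base, **raw}
    rs = QualityRuleSet.from_dict(merged)
    defects = check_ruleset(rs)
    if "label_vocabulary" in raw:
        # A user-supplied vocabulary replaces the defaults wholesale, so it
        # must cover every (cancer type, modality) combination.
        from .repo_model import MODALITY_CODES
        for cancer in CANCER_TYPES:
            for modality in MODALITY_CODES:
                if (cancer, modality) not in rs.label_vocabulary:
                    defects.append(
                        f"label_vocabulary missing entry for {cancer}/{modality}")
    if defects:
        raise RulesetError(f"{path}: " + "; ".join(defects))
    return rs


def check_ruleset(ruleset: QualityRuleSet) -> list[str]:
    """Return the list of invariant violations (empty iff the rule-set is sound)."""
    defects: list[str] = []
    for cancer, fields_ in ruleset.mandatory_fields.items():
        for f in fields_:
            if f not in ruleset.field_rules:
                defects.append(
                    f"mandatory field '{f}' ({cancer}) missing from field_rules")
    for rule in ruleset.crosslink_rules:
        for f in (rule.when_field, rule.require_field):
            if f not in ruleset.field_rules:
                defects.append(
                    f"crosslink rule '{rule.name}' references unknown field '{f}'")
        if rule.requirement not in ("missing", "nonmissing", "equals"):
            defects.append(
                f"crosslink rule '{rule.name}': unknown requirement "
                f"'{rule.requirement}'")
    for (cancer, modality), entries in ruleset.label_vocabulary.items():
        for code, entry in entries.items():
            if code <= 0:
                defects.append(
                    f"label code {code} for {cancer}/{modality} must be positive")
            if entry.klass not in LABEL_CLASSES:
                defects.append(
                    f"label class '{entry.klass}' for {cancer}/{modality}:{code} "
                    f"not in {LABEL_CLASSES}")
    if not ruleset.dedup.high < ruleset.dedup.normal:
        defects.append(
            f"dedup thresholds out of order: high={ruleset.dedup.high} must be "
            f"< normal={ruleset.dedup.normal}")
    if ruleset.age_bin_edges != sorted(ruleset.age_bin_edges):
        defects.append("age_bin_edges must be increasing")
    if not 0 < ruleset.dominance_share <= 1:
        defects.append("dominance_share must be in (0, 1]")
    return defects


def require_vocabulary(ruleset: QualityRuleSet, cancer: str,
                       modality: str) -> dict[int, LabelEntry]:
    vocab = ruleset.label_vocabulary.get((cancer, modality))
    if vocab is None:
        raise RulesetError(
            f"no label vocabulary configured for {cancer}/{modality}")
    return vocab


def save_ruleset(ruleset: QualityRuleSet, path: Path) -> None:
    path = Path(path)
    data = ruleset.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
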