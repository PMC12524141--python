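"""Rule-based clinical-metadata quality metrics.

Four count-based dimensions over the clinical template and the scanned
repository index:

* **completeness** — record = patient; passes iff every mandatory field is
  non-missing and imaging exists at a timepoint beyond diagnosis.
* **validity** — record = each inserted (non-missing) value in a constrained
  field; passes iff type, format and range/allowed-set all hold.  Missing
  values are completeness's concern and never enter this denominator.
* **consistency** — record = each applicable cross-link rule evaluation per
  patient (applicable when the condition field is non-missing).
* **integrity** — record = each provided modality instance per
  (patient, timepoint); passes iff declared, declared series count matches the
  provided count, and the directory obeys the naming convention.  A declared
  but absent modality adds a failing record (configurable).

Percentages are rounded half-up to two decimals, matching how normalized
result tables are printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .repo_model import ClinicalTable, RepositoryIndex
from .rules_config import QualityRuleSet


def round_half_up(value, decimals: int = 2) -> float:
    """Round with ties away from zero (half-up), as printed tables do."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def ratio_percentage(numerator: int, denominator: int,
                     decimals: int = 2) -> Optional[float]:
    """Exact-rational percentage, half-up; ``None`` when the denominator is 0."""
    if denominator == 0:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100 * numerator) / Decimal(denominator))
                 .quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RecordFlag:
    record_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class MetricResult:
    """Numerator/denominator/percentage plus per-record flags for one dimension."""

    dimension: str
    numerator: int
    denominator: int
    flags: list[RecordFlag] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(
                f"{self.dimension}: numerator {self.numerator} outside "
                f"[0, {self.denominator}]")

    @property
    def percentage(self) -> Optional[float]:
        """Percent passing, 2 decimals; ``None`` (undefined) when denominator is 0."""
        return ratio_percentage(self.numerator, self.denominator)

    @property
    def failing(self) -> list[RecordFlag]:
        return [f for f in self.flags if not f.passed]

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "percentage": self.percentage,
            "failing_records": [
                {"record": f.record_id, "reasons": f.reasons} for f in self.failing],
            "warnings": list(self.warnings),
        }


def _from_flags(dimension: str, flags: list[RecordFlag],
                warnings: Optional[list[str]] = None) -> MetricResult:
    return MetricResult(
        dimension=dimension,
        numerator=sum(1 for f in flags if f.passed),
        denominator=len(flags),
        flags=flags,
        warnings=warnings or [],
    )


# ---------------------------------------------------------------------------


def completeness(table: ClinicalTable, index: RepositoryIndex,
                 ruleset: QualityRuleSet) -> MetricResult:
    """Percentage of patients with all mandatory fields present and
    follow-up imaging beyond the diagnosis timepoint."""
    flags: list[RecordFlag] = []
    for rec in table.records():
        pid = rec[table.schema.patient_id_column]
        cancer = rec.get(table.schema.cancer_type_column)
        mandatory = ruleset.mandatory_fields.get(str(cancer), [])
        reasons = [f"missing mandatory field '{f}'"
                   for f in mandatory if rec.get(f) is None]
        patient = index.get_patient(str(pid))
        if patient is None:
            reasons.append("no follow-up timepoint (patient absent from repository)")
        elif not patient.has_followup_imaging:
            reasons.append("no follow-up timepoint")
        flags.append(RecordFlag(record_id=str(pid), passed=not reasons,
                                reasons=reasons))
    return _from_flags("completeness", flags)


def validity(table: ClinicalTable, ruleset: QualityRuleSet) -> MetricResult:
    """Percentage of inserted values conforming to their field rules."""
    flags: list[RecordFlag] = []
    assessed = [(name, rule) for name, rule in ruleset.field_rules.items()
                if rule.constrained]
    for rec in table.records():
        pid = rec[table.schema.patient_id_column]
        for name, rule in assessed:
            if name not in table.df.columns:
                continue
            value = rec.get(name)
            if value is None:
                continue  # missing is completeness's concern
            ok = rule.is_valid(value)
            flags.append(RecordFlag(
                record_id=f"{pid}/{name}", passed=ok,
                reasons=[] if ok else [f"value {value!r} violates rule for '{name}'"]))
    return _from_flags("validity", flags)


def consistency(table: ClinicalTable, ruleset: QualityRuleSet) -> MetricResult:
    """Percentage of applicable cross-link rule evaluations that hold."""
    warnings = []
    if not ruleset.crosslink_rules:
        warnings.append("no crosslink rules configured; consistency undefined")
        return _from_flags("consistency", [], warnings)
    flags: list[RecordFlag] = []
    for rec in table.records():
        pid = rec[table.schema.patient_id_column]
        for rule in ruleset.crosslink_rules:
            if not rule.applicable(rec):
                continue
            ok = rule.holds(rec)
            flags.append(RecordFlag(
                record_id=f"{pid}/{rule.name}", passed=ok,
                reasons=[] if ok else [f"crosslink rule '{rule.name}' violated"]))
    return _from_flags("consistency", flags, warnings)


def parse_declarations(value: Optional[str]) -> dict[str, int]:
    """Parse a declaration cell like ``"CT:2;MR"`` into {modality: series count}."""
    if value is None:
        return {}
    out: dict[str, int] = {}
    for item in str(value).split(";"):
        item = item.strip()
        if not item:
            continue
        if ":" in item:
            mod, _, cnt = item.partition(":")
            try:
                out[mod.strip()] = int(cnt)
            except ValueError:
                out[mod.strip()] = 1
        else:
            out[item] = 1
    return out


def integrity(table: ClinicalTable, index: RepositoryIndex,
              ruleset: QualityRuleSet) -> MetricResult:
    """Percentage of modality records properly integrated between the
    clinical template declarations and the provided imaging directories."""
    flags: list[RecordFlag] = []
    for rec in table.records():
        pid = str(rec[table.schema.patient_id_column])
        patient = index.get_patient(pid)
        timepoints = sorted(set(ruleset.modality_declaration_fields)
                            | set(patient.timepoints if patient else []))
        for tp in timepoints:
            column = ruleset.modality_declaration_fields.get(tp)
            declared = parse_declarations(rec.get(column)) if column else {}
            provided = patient.modalities_at(tp) if patient else {}
            for mod in sorted(provided):
                series_list = provided[mod]
                reasons = []
                if mod not in declared:
                    reasons.append(f"provided modality {mod} not declared at T{tp}")
                elif declared[mod] != len(series_list):
                    reasons.append(
                        f"{mod} at T{tp}: declared {declared[mod]} series, "
                        f"provided {len(series_list)}")
                bad_names = [s.raw_modality_dirname for s in series_list
                             if s.naming_violation]
                if bad_names:
                    reasons.append(
                        f"naming convention violated: {sorted(set(bad_names))}")
                flags.append(RecordFlag(record_id=f"{pid}/T{tp}/{mod}",
                                        passed=not reasons, reasons=reasons))
            if ruleset.count_declared_absent:
                for mod in sorted(set(declared) - set(provided)):
                    flags.append(RecordFlag(
                        record_id=f"{pid}/T{tp}/{mod}", passed=False,
                        reasons=[f"declared modality {mod} absent at T{tp}"]))
    return _from_flags("integrity", flags)
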