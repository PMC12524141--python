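"""De-identification compliance audit (read-only).

Three violation categories per DICOM file:

* ``retained_attribute`` — a header attribute the de-identification profile
  requires to be absent (patient sex, age, name, birth date by default) is
  present.
* ``date_hash_mismatch`` — date tags must be offset-hashed with the patient
  ID: expected date = anchor + offset days where
  offset = int(sha256(patient_id)[:8 hex], 16) mod 365.  A file is flagged
  when the in-header patient ID differs from the folder-derived one, or when
  its observed offset differs from the expected per-patient offset (which also
  catches offsets mutually inconsistent across one patient's files).
* ``burnt_in_report`` — pixel data that looks like a rendered report page
  rather than an organ: candidates come from header hints (burned-in
  annotation tag, secondary-capture SOP class, modality OT) or a
  recall-oriented pixel screen, and are then classified by a two-threshold
  histogram heuristic on the intensity spectrum: report iff at least half the
  pixels sit within 5% of full range of the modal intensity AND the image
  uses at most 64 distinct 8-bit levels.

The anonymization metric treats each DICOM file as one record, failing iff it
carries at least one violation of any category.  All audits are advisory and
never modify input files.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np

from .clinical_metrics import MetricResult, RecordFlag
from .imaging_dedup import load_slice_pixels
from .repo_model import InstanceHeader, PatientEntry, RepositoryIndex, SeriesRecord
from .rules_config import DeidProfile, QualityRuleSet

logger = logging.getLogger(__name__)

SECONDARY_CAPTURE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"

#: classifier defaults (config-exposed through keyword arguments)
BACKGROUND_FRACTION_MIN = 0.5
BACKGROUND_BANDWIDTH = 0.05   # fraction of full range around the modal intensity
RICHNESS_MAX = 64             # distinct 8-bit levels


@dataclass
class DeidViolation:
    path: Path
    category: str  # retained_attribute | date_hash_mismatch | burnt_in_report
    detail: str
    severity: str = "error"

    def to_dict(self) -> dict:
        return {"path": str(self.path), "category": self.category,
                "detail": self.detail, "severity": self.severity}


def expected_offset(patient_id: str, modulus: int = 365) -> int:
    """Per-patient day offset derived from the patient ID."""
    digest = hashlib.sha256(patient_id.encode("utf-8")).hexdigest()
    return int(digest[:8], 16) % modulus


def hashed_date(patient_id: str, profile: DeidProfile) -> date:
    """The date value a compliant de-identification writes for this patient."""
    return profile.anchor() + timedelta(
        days=expected_offset(patient_id, profile.offset_modulus))


def _parse_dicom_date(value: str) -> Optional[date]:
    try:
        return datetime.strptime(value.strip(), "%Y%m%d").date()
    except (ValueError, AttributeError):
        return None


def audit_removed_attributes(series: SeriesRecord,
                             profile: DeidProfile) -> list[DeidViolation]:
    """One violation per present forbidden tag per instance."""
    field_of_tag = {
        "PatientSex": "patient_sex",
        "PatientAge": "patient_age",
        "PatientName": "patient_name",
        "PatientBirthDate": "patient_birth_date",
    }
    violations = []
    for inst in series.instances:
        for tag in profile.forbidden_tags:
            value = getattr(inst, field_of_tag.get(tag, ""), None)
            if value not in (None, ""):
                violations.append(DeidViolation(
                    path=inst.path, category="retained_attribute",
                    detail=f"{tag} present (value {value!r})"))
    return violations


def audit_date_hashing(patient: PatientEntry,
                       profile: DeidProfile) -> list[DeidViolation]:
    """Check id-match and per-patient offset consistency of hashed dates.

    The folder-derived patient id is authoritative; undated files are skipped.
    """
    folder_pid = patient.patient_id
    expected = expected_offset(folder_pid, profile.offset_modulus)
    anchor = profile.anchor()
    violations = []
    for series in patient.iter_series():
        for inst in series.instances:
            if inst.patient_id is not None and inst.patient_id != folder_pid:
                violations.append(DeidViolation(
                    path=inst.path, category="date_hash_mismatch",
                    detail=(f"header PatientID {inst.patient_id!r} differs from "
                            f"folder id {folder_pid!r}")))
                continue
            for tag in profile.date_tags:
                raw = inst.dates.get(tag)
                if raw is None:
                    continue
                parsed = _parse_dicom_date(raw)
                if parsed is None:
                    violations.append(DeidViolation(
                        path=inst.path, category="date_hash_mismatch",
                        detail=f"{tag} value {raw!r} is not a parseable date"))
                    continue
                observed = (parsed - anchor).days % profile.offset_modulus
                if observed != expected:
                    violations.append(DeidViolation(
                        path=inst.path, category="date_hash_mismatch",
                        detail=(f"{tag}: observed offset {observed} d differs "
                                f"from expected {expected} d for "
                                f"patient {folder_pid!r}")))
    return violations


# ---------------------------------------------------------------------------
# Burnt-in report detection


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.clip(np.rint((arr - lo) * (255.0 / (hi - lo))), 0, 255).astype(np.uint8)


def classify_report_image(pixels: np.ndarray,
                          background_fraction_min: float = BACKGROUND_FRACTION_MIN,
                          background_bandwidth: float = BACKGROUND_BANDWIDTH,
                          richness_max: int = RICHNESS_MAX) -> str:
    """Classify a candidate image as ``"report"`` or ``"organ"``.

    Report iff BOTH hold on the 8-bit min-max-scaled image: the share of
    pixels within ``background_bandwidth`` of full range around the modal
    intensity is at least ``background_fraction_min``, and the number of
    distinct 8-bit levels is at most ``richness_max``.  A constant image is
    all background, hence a report.
    """
    arr = _to_uint8(pixels)
    values, counts = np.unique(arr, return_counts=True)
    mode = int(values[np.argmax(counts)])
    band = background_bandwidth * 255.0
    background = float(np.mean(np.abs(arr.astype(np.float64) - mode) <= band))
    richness = int(values.size)
    if background >= background_fraction_min and richness <= richness_max:
        return "report"
    return "organ"


@dataclass
class BurntInCandidate:
    path: Path
    reasons: list[str] = field(default_factory=list)
    classification: Optional[str] = None  # report | organ | None (unreadable)


def screen_burnt_in_candidates(series: SeriesRecord,
                               read_pixels: bool = True) -> list[BurntInCandidate]:
    """Recall-oriented screen for instances that may embed burnt-in text.

    Header hints (burned-in-annotation tag, secondary-capture SOP class,
    modality OT) or the pixel-spectrum screen make an instance a candidate;
    unreadable pixel data makes it a candidate by caution.
    """
    candidates = []
    for inst in series.instances:
        reasons = []
        if (inst.burned_in_annotation or "").upper() == "YES":
            reasons.append("burned-in-annotation tag set")
        if inst.sop_class_uid == SECONDARY_CAPTURE_SOP_CLASS:
            reasons.append("secondary-capture SOP class")
        if (inst.modality or "").upper() == "OT":
            reasons.append("modality OT")
        classification = None
        if read_pixels:
            try:
                pixels = load_slice_pixels(inst.path)
            except Exception as exc:
                reasons.append(f"unreadable pixel data ({exc})")
                candidates.append(BurntInCandidate(path=inst.path, reasons=reasons))
                continue
            classification = classify_report_image(pixels)
            if classification == "report":
                reasons.append("pixel spectrum matches a report page")
        if reasons:
            candidates.append(BurntInCandidate(
                path=inst.path, reasons=reasons, classification=classification))
    return candidates


def audit_burnt_in(series: SeriesRecord) -> list[DeidViolation]:
    """Burnt-in violations: candidates whose pixel data classifies as report."""
    violations = []
    for cand in screen_burnt_in_candidates(series, read_pixels=True):
        if cand.classification == "report":
            violations.append(DeidViolation(
                path=cand.path, category="burnt_in_report",
                detail="; ".join(cand.reasons)))
        elif cand.classification is None:
            violations.append(DeidViolation(
                path=cand.path, category="burnt_in_report",
                detail="; ".join(cand.reasons), severity="warning"))
    return violations


# ---------------------------------------------------------------------------


@dataclass
class DeidAuditResult:
    metric: MetricResult
    violations: list[DeidViolation]
    non_assessable: int = 0

    def by_category(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.violations:
            out[v.category] = out.get(v.category, 0) + 1
        return out

    def to_dict(self) -> dict:
        m = self.metric.to_dict()
        m["non_conformant_percentage"] = (
            None if self.metric.percentage is None
            else round(100.0 - self.metric.percentage, 2))
        return {
            "metric": m,
            "by_category": self.by_category(),
            "non_assessable": self.non_assessable,
            "violations": [v.to_dict() for v in self.violations],
        }


def anonymization_metric(index: RepositoryIndex, ruleset: QualityRuleSet,
                         check_burnt_in: bool = True) -> DeidAuditResult:
    """Record = DICOM file; a file fails iff it has any violation.

    The metric percentage is the compliant share; the non-conformant share is
    its complement, carried in the serialized result.  Unreadable files are
    excluded from pixel checks and reported as non-assessable.
    """
    profile = ruleset.deid_profile
    violations: list[DeidViolation] = []
    for prov in sorted(index.providers):
        for pid in sorted(index.providers[prov].patients):
            patient = index.providers[prov].patients[pid]
            violations.extend(audit_date_hashing(patient, profile))
            for series in patient.iter_series():
                violations.extend(audit_removed_attributes(series, profile))
                if check_burnt_in:
                    violations.extend(audit_burnt_in(series))
    violating_paths: dict[Path, list[str]] = {}
    for v in violations:
        violating_paths.setdefault(v.path, []).append(f"{v.category}: {v.detail}")
    flags = []
    for series, inst in index.iter_instances():
        reasons = violating_paths.get(inst.path, [])
        flags.append(RecordFlag(record_id=str(inst.path),
                                passed=not reasons, reasons=reasons))
    metric = MetricResult(
        dimension="anonymization",
        numerator=sum(1 for f in flags if f.passed),
        denominator=len(flags), flags=flags)
    return DeidAuditResult(metric=metric, violations=violations,
                           non_assessable=len(index.skipped_files))
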