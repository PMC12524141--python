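"""Annotation-mask quality checks.

Covers label-vocabulary conformance, geometric consistency between each mask
and its imaging series (in-plane dimensions and slice count from headers
only; spatial re-alignment by affines is a separate downstream step),
empty-mask detection, per-patient timepoint coverage, and the
malignant/benign label summary.

The counting unit of the label summary is one (mask file, distinct nonzero
label code) instance; connected-component lesion counting is deliberately not
required.  The summary's ``n`` counts every classified label instance
(malignant, benign and other classes alike) while only the malignant and
benign shares are reported, so the two percentages sum to 100 only when no
other-class labels are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .clinical_metrics import MetricResult, RecordFlag, ratio_percentage
from .repo_model import AnnotationVolume, RepositoryIndex, SeriesRecord
from .rules_config import LabelEntry, QualityRuleSet, require_vocabulary


class GeometryStatus(str, Enum):
    CONSISTENT = "consistent"
    ROI_MISMATCH = "roi_mismatch"
    SLICE_MISMATCH = "slice_mismatch"
    BOTH_MISMATCH = "both_mismatch"


@dataclass
class ConsistencyStatus:
    status: GeometryStatus
    mask_dims: tuple[int, int, int]
    series_dims: tuple[Optional[int], Optional[int], int]

    @property
    def consistent(self) -> bool:
        return self.status is GeometryStatus.CONSISTENT


@dataclass
class LabelViolation:
    path: str
    code: int
    voxel_count: int


def check_label_vocabulary(annotation: AnnotationVolume,
                           vocab: dict[int, LabelEntry]) -> list[LabelViolation]:
    """Every nonzero label code must be in the vocabulary."""
    violations = []
    for code in sorted(annotation.labels - {0}):
        if code not in vocab:
            violations.append(LabelViolation(
                path=str(annotation.path), code=code,
                voxel_count=int(np.count_nonzero(annotation.data == code))))
    return violations


def check_geometry_consistency(annotation: AnnotationVolume,
                               series: SeriesRecord) -> ConsistencyStatus:
    """Consistent iff in-plane dimensions and slice counts both match."""
    inst = series.instances[0] if series.instances else None
    rows = inst.rows if inst else None
    cols = inst.columns if inst else None
    roi_ok = (rows == annotation.rows and cols == annotation.columns)
    slices_ok = (series.instance_count == annotation.slice_count)
    if roi_ok and slices_ok:
        status = GeometryStatus.CONSISTENT
    elif roi_ok:
        status = GeometryStatus.SLICE_MISMATCH
    elif slices_ok:
        status = GeometryStatus.ROI_MISMATCH
    else:
        status = GeometryStatus.BOTH_MISMATCH
    return ConsistencyStatus(
        status=status,
        mask_dims=(annotation.rows, annotation.columns, annotation.slice_count),
        series_dims=(rows, cols, series.instance_count))


def is_empty_annotation(annotation: AnnotationVolume) -> bool:
    """True iff every voxel is zero (no region required annotation)."""
    return annotation.labels <= {0}


@dataclass
class CoverageRow:
    cancer: str
    modality: str
    k_timepoints: int
    patient_count: int


def timepoint_coverage(index: RepositoryIndex,
                       cancer_of_patient: dict[str, str] | None = None,
                       ) -> list[CoverageRow]:
    """Patients per (cancer, modality, number of distinct annotated timepoints).

    Rows are mutually exclusive per (patient, modality): a patient counts once
    under k = the number of distinct timepoints holding at least one
    annotation for that modality.
    """
    cancer_of_patient = cancer_of_patient or {}
    counter: dict[tuple[str, str, int], int] = {}
    for prov in sorted(index.providers):
        for pid in sorted(index.providers[prov].patients):
            patient = index.providers[prov].patients[pid]
            annotated_tps: dict[str, set[int]] = {}
            for series in patient.iter_series():
                if series.mask_paths and series.timepoint is not None:
                    annotated_tps.setdefault(series.modality, set()).add(
                        series.timepoint)
            cancer = cancer_of_patient.get(pid, "unknown")
            for modality, tps in annotated_tps.items():
                key = (cancer, modality, len(tps))
                counter[key] = counter.get(key, 0) + 1
    return [CoverageRow(cancer=c, modality=m, k_timepoints=k, patient_count=n)
            for (c, m, k), n in sorted(counter.items())]


@dataclass
class LabelClassSummary:
    cancer: str
    modality: str
    malignant_count: int
    benign_count: int
    n: int  # all classified label instances, other classes included
    warnings: list[str] = field(default_factory=list)

    @property
    def malignant_pct(self) -> Optional[float]:
        return ratio_percentage(self.malignant_count, self.n, decimals=1)

    @property
    def benign_pct(self) -> Optional[float]:
        return ratio_percentage(self.benign_count, self.n, decimals=1)

    def to_dict(self) -> dict:
        return {"cancer": self.cancer, "modality": self.modality,
                "malignant_pct": self.malignant_pct,
                "benign_pct": self.benign_pct, "n": self.n}


def label_class_summary(annotations: Sequence[AnnotationVolume],
                        vocab: dict[int, LabelEntry],
                        cancer: str = "", modality: str = "") -> LabelClassSummary:
    """Malignant/benign shares of label instances for one (cancer, modality)."""
    malignant = benign = n = 0
    warnings = []
    for ann in annotations:
        for code in sorted(ann.labels - {0}):
            entry = vocab.get(code)
            if entry is None:
                continue  # unknown codes are vocabulary violations, not classes
            n += 1
            if entry.klass == "malignant":
                malignant += 1
            elif entry.klass == "benign":
                benign += 1
    if n == 0:
        warnings.append(f"no classified label instances for {cancer}/{modality}; "
                        "summary undefined")
    return LabelClassSummary(cancer=cancer, modality=modality,
                             malignant_count=malignant, benign_count=benign,
                             n=n, warnings=warnings)


@dataclass
class AnnotationFindings:
    """Per-mask findings plus the annotation-consistency metric."""

    consistency: MetricResult
    empty_rate: Optional[float]
    empty_count: int
    mask_count: int
    label_violations: list[LabelViolation] = field(default_factory=list)
    orphans: list[str] = field(default_factory=list)
    statuses: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "consistency": self.consistency.to_dict(),
            "empty_rate": self.empty_rate,
            "empty_count": self.empty_count,
            "mask_count": self.mask_count,
            "label_violations": [vars(v).copy() for v in self.label_violations],
            "orphans": list(self.orphans),
        }


def evaluate_annotations(index: RepositoryIndex, ruleset: QualityRuleSet,
                         cancer_of_patient: dict[str, str] | None = None,
                         ) -> AnnotationFindings:
    """Run geometry, emptiness and vocabulary checks over all linked masks."""
    from .repo_model import load_annotations
    cancer_of_patient = cancer_of_patient or {}
    flags: list[RecordFlag] = []
    label_violations: list[LabelViolation] = []
    statuses: dict[str, str] = {}
    empty = 0
    series_by_path = {s.path: s for s in index.iter_series()}
    annotations = load_annotations(index)
    for ann in annotations:
        series = series_by_path.get(ann.series_path)
        if series is None:  # orphan; routed to integrity reason codes upstream
            continue
        status = check_geometry_consistency(ann, series)
        statuses[str(ann.path)] = status.status.value
        flags.append(RecordFlag(
            record_id=str(ann.path), passed=status.consistent,
            reasons=[] if status.consistent else [status.status.value]))
        if is_empty_annotation(ann):
            empty += 1
        cancer = cancer_of_patient.get(series.patient_id)
        if cancer is not None:
            try:
                vocab = require_vocabulary(ruleset, cancer, series.modality)
            except Exception:
                vocab = None
            if vocab is not None:
                label_violations.extend(check_label_vocabulary(ann, vocab))
    n = len(flags)
    consistency = MetricResult(
        dimension="annotation_consistency",
        numerator=sum(1 for f in flags if f.passed),
        denominator=n, flags=flags)
    return AnnotationFindings(
        consistency=consistency,
        empty_rate=ratio_percentage(empty, n, decimals=1),
        empty_count=empty, mask_count=n,
        label_violations=label_violations,
        statuses=statuses)
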