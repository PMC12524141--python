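"""Annotation geometry, emptiness, vocabulary and label summaries."""

from __future__ import annotations

import numpy as np
import pytest

from cimqc import default_ruleset, evaluate_annotations, label_class_summary
from cimqc.annotation_qc import (GeometryStatus, check_geometry_consistency,
                                 check_label_vocabulary, is_empty_annotation,
                                 timepoint_coverage)
from cimqc.repo_model import AnnotationVolume, InstanceHeader, SeriesRecord
from cimqc.rules_config import LabelEntry


def _vol(rows=32, cols=32, slices=2, labels=(0, 3)):
    data = np.zeros((rows, cols, slices), dtype=np.int32)
    for i, lab in enumerate(sorted(set(labels) - {0})):
        data[1 + i, 1, 0] = lab
    return AnnotationVolume(path="m.nii.gz", rows=rows, columns=cols,
                            slice_count=slices, labels=frozenset(labels),
                            data=data)


def _series(rows=32, cols=32, slices=2):
    insts = [InstanceHeader(path=f"I{i}.dcm", rows=rows, columns=cols)
             for i in range(slices)]
    return SeriesRecord(path="S0", provider_id="DP1", patient_id="P1",
                        timepoint=1, modality="CT", series_id="S0",
                        instances=insts)


@pytest.mark.parametrize("rows,slices,status", [
    (32, 2, GeometryStatus.CONSISTENT),
    (16, 2, GeometryStatus.ROI_MISMATCH),
    (32, 5, GeometryStatus.SLICE_MISMATCH),
    (16, 5, GeometryStatus.BOTH_MISMATCH),
])
def test_geometry_statuses(rows, slices, status):
    res = check_geometry_consistency(_vol(rows=rows, slices=slices), _series())
    assert res.status is status
    assert res.consistent == (status is GeometryStatus.CONSISTENT)


def test_empty_annotation():
    assert is_empty_annotation(_vol(labels=(0,)))
    assert not is_empty_annotation(_vol(labels=(0, 1)))


def test_label_vocabulary_violations():
    vocab = {1: LabelEntry(1, "Benign", "benign"),
             3: LabelEntry(3, "Malignant", "malignant")}
    violations = check_label_vocabulary(_vol(labels=(0, 3, 9)), vocab)
    assert [v.code for v in violations] == [9]
    assert violations[0].voxel_count > 0


def test_label_class_summary_worked_example():
    vocab = {1: LabelEntry(1, "Benign", "benign"),
             3: LabelEntry(3, "Malignant", "malignant")}
    anns = [_vol(labels=(0, 3)) for _ in range(305)] + \
        [_vol(labels=(0, 1)) for _ in range(5)]
    summary = label_class_summary(anns, vocab, "lung", "CT")
    assert summary.n == 310
    assert summary.malignant_pct == 98.4
    assert summary.benign_pct == 1.6


def test_label_summary_n_includes_other_classes():
    vocab = {1: LabelEntry(1, "Benign", "benign"),
             2: LabelEntry(2, "Suspicious", "other"),
             3: LabelEntry(3, "Malignant", "malignant")}
    anns = [_vol(labels=(0, 2, 3))]
    summary = label_class_summary(anns, vocab, "breast", "CT")
    assert summary.n == 2  # the "other" instance counts toward n
    assert summary.malignant_pct == 50.0


def test_label_summary_empty_undefined():
    summary = label_class_summary([], {}, "lung", "CT")
    assert summary.n == 0
    assert summary.malignant_pct is None
    assert summary.warnings


def test_evaluate_annotations_matches_manifest(small_repo, small_index,
                                               small_table, ruleset):
    _, manifest = small_repo
    cancer_of = {str(r["patient_id"]): str(r["cancer_type"])
                 for r in small_table.records()}
    findings = evaluate_annotations(small_index, ruleset, cancer_of)
    assert findings.consistency.percentage == \
        manifest.expected["annotation_consistency"]
    assert findings.empty_rate == manifest.expected["empty_mask_rate"]
    planted_unknown = manifest.defect_records("unknown_label")
    flagged_unknown = {v.path for v in findings.label_violations}
    assert len(flagged_unknown) == len(planted_unknown)
    # each flagged path belongs to a planted series record
    root = str(small_repo[0])
    for rec in planted_unknown:
        assert any(rec.split("/")[-1] in p for p in flagged_unknown), rec


def test_timepoint_coverage(small_index, small_table):
    cancer_of = {str(r["patient_id"]): str(r["cancer_type"])
                 for r in small_table.records()}
    rows = timepoint_coverage(small_index, cancer_of)
    # every patient with masks at both T1 and T2 is a k=2 row member
    total = sum(r.patient_count for r in rows)
    assert total == small_index.patient_count  # all patients annotated (CT only)
    assert all(r.k_timepoints in (1, 2) for r in rows)
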