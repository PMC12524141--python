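"""Repository scanning, readers and clinical-table normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cimqc import (LayoutSpec, RepositoryError, load_clinical_table,
                   read_annotation, scan_repository)
from cimqc.repo_model import TemplateSchema, read_series_header


def test_scan_counts_match_manifest(small_repo, small_index):
    _, manifest = small_repo
    assert small_index.patient_count == manifest.counts["patients"]
    assert small_index.series_count == manifest.counts["series"]
    assert small_index.instance_count == manifest.counts["files"]


def test_scan_is_deterministic(small_repo):
    root, _ = small_repo
    a = scan_repository(root)
    b = scan_repository(root)
    assert [s.path for s in a.iter_series()] == [s.path for s in b.iter_series()]
    assert [i.media_storage_sop_uid for _, i in a.iter_instances()] == \
        [i.media_storage_sop_uid for _, i in b.iter_instances()]


def test_series_headers_carry_audit_tags(small_index):
    series = next(small_index.iter_series())
    inst = series.instances[0]
    assert inst.media_storage_sop_uid
    assert inst.rows and inst.columns
    assert "StudyDate" in inst.dates


def test_naming_violation_indexed_not_dropped(small_repo, small_index):
    _, manifest = small_repo
    planted = manifest.defect_records("naming_violation")
    flagged = {f"{s.patient_id}/T{s.timepoint}/{s.modality}"
               for s in small_index.iter_series() if s.naming_violation}
    assert flagged == set(planted)


def test_normalize_modality():
    layout = LayoutSpec()
    assert layout.normalize_modality("CT") == ("CT", True)
    assert layout.normalize_modality("ct_scan") == ("CT", False)
    assert layout.normalize_modality("FUSCT") == ("FUSCT", True)
    # longest-prefix wins: FUSCT_x must not be read as a malformed CT
    assert layout.normalize_modality("fusct_x") == ("FUSCT", False)


def test_missing_root_raises(tmp_path):
    with pytest.raises(RepositoryError):
        scan_repository(tmp_path / "nope")


def test_empty_series_dir_is_warned_not_fatal(small_repo):
    root, _ = small_repo
    with pytest.raises(RepositoryError):
        read_series_header(root)  # root has no .dcm files


def test_read_annotation_2d_promoted(tmp_path):
    import nibabel as nib
    arr = np.zeros((8, 8), dtype=np.int16)
    arr[2:4, 2:4] = 2
    nib.save(nib.Nifti1Image(arr, np.eye(4)), tmp_path / "m.nii.gz")
    vol = read_annotation(tmp_path / "m.nii.gz")
    assert (vol.rows, vol.columns, vol.slice_count) == (8, 8, 1)
    assert vol.labels == {0, 2}


def test_read_annotation_negative_labels_fatal(tmp_path):
    import nibabel as nib
    arr = -np.ones((4, 4, 2), dtype=np.int16)
    nib.save(nib.Nifti1Image(arr, np.eye(4)), tmp_path / "neg.nii.gz")
    with pytest.raises(RepositoryError):
        read_annotation(tmp_path / "neg.nii.gz")


def test_nii_and_nii_gz_equivalent(tmp_path):
    import nibabel as nib
    arr = np.zeros((6, 6, 3), dtype=np.int16)
    arr[1:3, 1:3, 1] = 1
    nib.save(nib.Nifti1Image(arr, np.eye(4)), tmp_path / "a.nii")
    nib.save(nib.Nifti1Image(arr, np.eye(4)), tmp_path / "a2.nii.gz")
    va, vb = read_annotation(tmp_path / "a.nii"), read_annotation(tmp_path / "a2.nii.gz")
    assert np.array_equal(va.data, vb.data)
    assert va.labels == vb.labels


def test_clinical_missing_sentinels_normalized(tmp_path):
    path = tmp_path / "clinical_breast.csv"
    path.write_text("patient_id,provider_id,cancer_type,sex,age\n"
                    "P1,DP1,breast,,55\n"
                    "P2,DP1,breast,NA,n/a\n"
                    "P3,DP1,breast,F,null\n")
    table = load_clinical_table(path, TemplateSchema(fields=("sex", "age")))
    recs = {r["patient_id"]: r for r in table.records()}
    assert recs["P1"]["sex"] is None
    assert recs["P2"]["sex"] is None and recs["P2"]["age"] is None
    assert recs["P3"]["sex"] == "F" and recs["P3"]["age"] is None


def test_clinical_duplicate_patient_id_fatal(tmp_path):
    path = tmp_path / "clinical_lung.csv"
    path.write_text("patient_id,provider_id,cancer_type\nP1,DP1,lung\nP1,DP1,lung\n")
    with pytest.raises(RepositoryError):
        load_clinical_table(path, TemplateSchema())


def test_clinical_unknown_columns_flagged(tmp_path):
    path = tmp_path / "clinical_lung.csv"
    path.write_text("patient_id,provider_id,cancer_type,mystery\nP1,DP1,lung,x\n")
    table = load_clinical_table(path, TemplateSchema())
    assert table.unknown_columns == ["mystery"]


def test_followup_property(small_index):
    for prov in small_index.providers.values():
        for patient in prov.patients.values():
            assert patient.has_followup_imaging == any(
                tp > 1 for tp in patient.timepoints)
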