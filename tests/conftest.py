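"""Shared fixtures: one small defect-injected repository reused by all tests."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

from cimqc import (GenerationParams, default_ruleset, generate_repository,
                   scan_repository)
from cimqc.report import load_clinical_tables

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

#: defect rates of the shared small repository (20 patients, 40 series,
#: 84 files including duplicate copies, 40 masks)
SMALL_RATES = {
    "missing_mandatory": 0.1,
    "invalid_value": 0.1,
    "crosslink_break": 0.1,
    "modality_mismatch": 0.1,
    "naming_violation": 0.05,
    "retained_sex_tag": 0.05,
    "date_hash_wrong_id": 0.025,
    "burnt_in_report": 0.05,
    "mask_slice_mismatch": 0.1,
    "mask_roi_mismatch": 0.05,
    "empty_mask": 0.1,
    "unknown_label": 0.05,
    "duplicate_series_intra": 0.05,
    "duplicate_series_inter": 0.025,
}


@pytest.fixture(scope="session")
def small_repo(tmp_path_factory):
    """(root, manifest) of a 2-provider, 20-patient repository, seed 7."""
    out = tmp_path_factory.mktemp("small_repo")
    params = GenerationParams(seed=7, providers=2, patients_per_provider=10,
                              with_annotations=True, rates=dict(SMALL_RATES))
    return generate_repository(params, out)


@pytest.fixture(scope="session")
def small_index(small_repo):
    root, _ = small_repo
    return scan_repository(root)


@pytest.fixture(scope="session")
def small_table(small_index):
    return load_clinical_tables(small_index)


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture(scope="session")
def clean_repo(tmp_path_factory):
    """A defect-free repository: every metric should be exactly 100%."""
    out = tmp_path_factory.mktemp("clean_repo")
    params = GenerationParams(seed=3, providers=1, patients_per_provider=8,
                              with_annotations=True, rates={})
    return generate_repository(params, out)
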