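"""Count-based clinical metrics against the generator's ground truth."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cimqc import (ClinicalTable, completeness, consistency, integrity,
                   ratio_percentage, validity)
from cimqc.clinical_metrics import MetricResult, parse_declarations


def test_ratio_percentage_exact_and_undefined():
    assert ratio_percentage(110, 119) == 92.44
    assert ratio_percentage(4, 105) == 3.81
    assert ratio_percentage(1, 3) == 33.33
    assert ratio_percentage(0, 5) == 0.0
    assert ratio_percentage(0, 0) is None  # undefined, never 0 or 100
    assert ratio_percentage(305, 310, decimals=1) == 98.4


@given(st.integers(0, 10_000), st.integers(1, 10_000))
def test_ratio_percentage_bounds(num, den):
    num = min(num, den)
    pct = ratio_percentage(num, den)
    assert 0.0 <= pct <= 100.0
    if num == den:
        assert pct == 100.0


def test_metric_invariant_enforced():
    with pytest.raises(ValueError):
        MetricResult(dimension="x", numerator=5, denominator=3)


def test_parse_declarations():
    assert parse_declarations("CT:2;MR") == {"CT": 2, "MR": 1}
    assert parse_declarations("CT") == {"CT": 1}
    assert parse_declarations(None) == {}
    assert parse_declarations(" CT:1 ; MG:3 ") == {"CT": 1, "MG": 3}


def test_completeness_matches_manifest(small_repo, small_index, small_table,
                                       ruleset):
    _, manifest = small_repo
    result = completeness(small_table, small_index, ruleset)
    assert result.percentage == manifest.expected["completeness"]
    failing = {f.record_id for f in result.failing}
    assert failing == set(manifest.defect_records("missing_mandatory"))


def test_validity_matches_manifest(small_repo, small_table, ruleset):
    _, manifest = small_repo
    result = validity(small_table, ruleset)
    assert result.percentage == manifest.expected["validity"]
    failing = {f.record_id for f in result.failing}
    assert failing == set(manifest.defect_records("invalid_value"))


def test_validity_excludes_missing_values(ruleset):
    df = pd.DataFrame([
        {"patient_id": "P1", "provider_id": "DP1", "cancer_type": "lung",
         "sex": "M", "age": None, "grade": "9"},
    ])
    result = validity(ClinicalTable.from_dataframe(df), ruleset)
    # age missing -> not assessed; sex valid, grade invalid
    assert result.denominator == 2 and result.numerator == 1


def test_consistency_matches_manifest(small_repo, small_table, ruleset):
    _, manifest = small_repo
    result = consistency(small_table, ruleset)
    assert result.percentage == manifest.expected["consistency"]
    failing = {f.record_id.split("/")[0] for f in result.failing}
    assert failing == set(manifest.defect_records("crosslink_break"))


def test_consistency_without_rules_is_undefined(small_table, ruleset):
    import dataclasses
    bare = dataclasses.replace(ruleset, crosslink_rules=[])
    result = consistency(small_table, bare)
    assert result.percentage is None
    assert result.warnings


def test_integrity_matches_manifest(small_repo, small_index, small_table,
                                    ruleset):
    _, manifest = small_repo
    result = integrity(small_table, small_index, ruleset)
    assert result.percentage == manifest.expected["integrity"]
    planted = (set(manifest.defect_records("modality_mismatch"))
               | set(manifest.defect_records("naming_violation")))
    assert {f.record_id for f in result.failing} == planted


def test_integrity_declared_absent_counts(small_index, small_table, ruleset):
    df = small_table.df.copy()
    # declare a modality never provided for the first patient
    df.loc[df.index[0], "modalities_t1"] = str(
        df.loc[df.index[0], "modalities_t1"]) + ";MG:1"
    table = ClinicalTable(df=df, schema=small_table.schema)
    base = integrity(small_table, small_index, ruleset)
    bumped = integrity(table, small_index, ruleset)
    assert bumped.denominator == base.denominator + 1
    assert bumped.numerator == base.numerator


def test_clean_repo_all_metrics_100(clean_repo, ruleset):
    from cimqc import scan_repository
    from cimqc.report import load_clinical_tables
    root, _ = clean_repo
    index = scan_repository(root)
    table = load_clinical_tables(index)
    assert completeness(table, index, ruleset).percentage == 100.0
    assert validity(table, ruleset).percentage == 100.0
    assert consistency(table, ruleset).percentage == 100.0
    assert integrity(table, index, ruleset).percentage == 100.0


def test_row_order_invariance(small_repo, small_index, small_table, ruleset):
    shuffled = ClinicalTable(
        df=small_table.df.sample(frac=1.0, random_state=5).reset_index(drop=True),
        schema=small_table.schema)
    for fn in (lambda t: completeness(t, small_index, ruleset),
               lambda t: validity(t, ruleset),
               lambda t: consistency(t, ruleset),
               lambda t: integrity(t, small_index, ruleset)):
        a, b = fn(small_table), fn(shuffled)
        assert (a.numerator, a.denominator) == (b.numerator, b.denominator)
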