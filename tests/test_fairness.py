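"""Fairness distributions: binning, normalization and flags."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cimqc import (ClinicalTable, assign_age_bin, default_ruleset,
                   fairness_report, subgroup_distribution)
from cimqc.fairness import age_bin_labels

EDGES = list(range(20, 100, 5))


def _table(rows):
    return ClinicalTable.from_dataframe(pd.DataFrame(rows))


def test_age_bins_left_open_right_closed():
    assert assign_age_bin(20, EDGES) == "≤20"
    assert assign_age_bin(20.5, EDGES) == "(20, 25]"
    assert assign_age_bin(25, EDGES) == "(20, 25]"
    assert assign_age_bin(25.01, EDGES) == "(25, 30]"
    assert assign_age_bin(95, EDGES) == "(90, 95]"
    assert assign_age_bin(96, EDGES) == ">95"
    with pytest.raises(ValueError):
        assign_age_bin(-1, EDGES)


@given(st.floats(min_value=0, max_value=130, allow_nan=False))
def test_every_age_lands_in_exactly_one_bin(age):
    bin_ = assign_age_bin(age, EDGES)
    assert bin_ in age_bin_labels(EDGES)


def test_grade_distribution_worked_example():
    # 14 patients graded 8/5/1 across grades 1-3
    rows = [{"patient_id": f"P{i}", "provider_id": "DP1",
             "cancer_type": "colorectal",
             "grade": "1" if i < 8 else ("2" if i < 13 else "3")}
            for i in range(14)]
    dist = subgroup_distribution(_table(rows), "cancer_grade", "DP1")
    pct = dist.percentages
    assert pct["1"] == 57.14 and pct["2"] == 35.71 and pct["3"] == 7.14


def test_sex_distribution_worked_example():
    rows = [{"patient_id": f"P{i}", "provider_id": "DP3",
             "cancer_type": "colorectal", "sex": "M" if i < 47 else "F"}
            for i in range(80)]
    dist = subgroup_distribution(_table(rows), "sex", "DP3")
    assert dist.percentages == {"M": 58.75, "F": 41.25}


def test_single_class_site_is_100():
    rows = [{"patient_id": f"P{i}", "provider_id": "DP1",
             "cancer_type": "lung", "grade": "2"} for i in range(9)]
    dist = subgroup_distribution(_table(rows), "cancer_grade", "DP1")
    assert dist.percentages["2"] == 100.0


def test_missing_excluded_from_denominator():
    rows = [{"patient_id": "P1", "provider_id": "DP1", "cancer_type": "lung",
             "sex": "M"},
            {"patient_id": "P2", "provider_id": "DP1", "cancer_type": "lung",
             "sex": None}]
    dist = subgroup_distribution(_table(rows), "sex", "DP1")
    assert dist.total == 1 and dist.missing == 1
    assert dist.percentages["M"] == 100.0


def test_zero_value_site_flagged_missing_variable():
    rows = [{"patient_id": "P1", "provider_id": "DP1", "cancer_type": "lung",
             "sex": None, "age": None, "grade": None,
             "histological_type": None}]
    report = fairness_report(_table(rows), default_ruleset())
    kinds = {(f.variable, f.kind) for f in report.flags}
    assert ("sex", "missing_variable") in kinds


def test_dominance_flag():
    rows = [{"patient_id": f"P{i}", "provider_id": "DP1", "cancer_type": "lung",
             "sex": "M" if i < 9 else "F"} for i in range(10)]
    report = fairness_report(_table(rows), default_ruleset())
    assert any(f.kind == "dominance" and f.variable == "sex"
               for f in report.flags)


def test_prostate_sex_not_dominance_flagged():
    rows = [{"patient_id": f"P{i}", "provider_id": "DP1",
             "cancer_type": "prostate", "sex": "M"} for i in range(10)]
    report = fairness_report(_table(rows), default_ruleset())
    assert not any(f.kind == "dominance" and f.variable == "sex"
                   for f in report.flags)
    # absent class F is still surfaced
    assert any(f.kind == "absent_subgroup" and f.variable == "sex"
               for f in report.flags)


def test_permutation_invariance(small_table, ruleset):
    shuffled = ClinicalTable(
        df=small_table.df.sample(frac=1.0, random_state=11).reset_index(drop=True),
        schema=small_table.schema)
    a = fairness_report(small_table, ruleset)
    b = fairness_report(shuffled, ruleset)
    assert a.to_dict() == b.to_dict()


def test_per_site_counts_sum_to_global(small_table, ruleset):
    sites = sorted({str(r["provider_id"]) for r in small_table.records()})
    per_site = [subgroup_distribution(small_table, "sex", s, ruleset)
                for s in sites]
    global_count = sum(1 for r in small_table.records()
                       if r.get("sex") is not None)
    assert sum(d.total for d in per_site) == global_count


def test_manifest_composition_recovered(small_repo, small_table, ruleset):
    """Generated per-provider sex counts reappear in the distributions."""
    root, manifest = small_repo
    comp = manifest.counts.get("sex_by_provider", {})
    for site, expected in comp.items():
        dist = subgroup_distribution(small_table, "sex", site, ruleset)
        for cls, n in expected.items():
            assert dist.counts.get(cls, 0) == n
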