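"""Rule-set loading, validation and round-trips."""

from __future__ import annotations

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cimqc import (FieldRule, QualityRuleSet, RulesetError, check_ruleset,
                   default_ruleset, load_ruleset, save_ruleset)
from cimqc.rules_config import CrosslinkRule, require_vocabulary


def test_default_ruleset_is_sound():
    assert check_ruleset(default_ruleset()) == []


def test_roundtrip_dict():
    rs = default_ruleset()
    again = QualityRuleSet.from_dict(rs.to_dict())
    assert again.to_dict() == rs.to_dict()


def test_roundtrip_yaml_and_json(tmp_path):
    rs = default_ruleset()
    for name in ("r.yaml", "r.json"):
        save_ruleset(rs, tmp_path / name)
        loaded = load_ruleset(tmp_path / name)
        assert loaded.to_dict() == rs.to_dict()


def test_field_rule_constrained():
    assert not FieldRule(type="free-text").constrained
    assert FieldRule(type="free-text", pattern=r"\d+").constrained
    assert FieldRule(type="integer").constrained
    assert FieldRule(type="categorical", allowed=["a"]).constrained
    assert not FieldRule(type="categorical").constrained


def test_field_rule_validation():
    age = FieldRule(type="integer", min=0, max=120)
    assert age.is_valid("55") and age.is_valid(0)
    assert not age.is_valid("-1") and not age.is_valid("121")
    assert not age.is_valid("fifty")
    stage = FieldRule(type="categorical", allowed=["I", "II", "III", "IV"])
    assert stage.is_valid("II") and not stage.is_valid("3")
    d = FieldRule(type="date")
    assert d.is_valid("2021-05-01") and d.is_valid("20210501")
    assert not d.is_valid("01/05/2021")


def test_crosslink_semantics():
    rule = CrosslinkRule(name="r", when_field="biopsy", when_equals="No Biopsy",
                         require_field="her2_status", requirement="missing")
    assert not rule.applicable({"biopsy": None})
    assert rule.holds({"biopsy": "Biopsy", "her2_status": "positive"})
    assert rule.holds({"biopsy": "No Biopsy", "her2_status": None})
    assert not rule.holds({"biopsy": "No Biopsy", "her2_status": "positive"})


def test_unknown_field_rule_key_rejected(tmp_path):
    cfg = tmp_path / "bad.json"
    cfg.write_text(json.dumps({"field_rules": {"age": {"typ": "integer"}}}))
    with pytest.raises(RulesetError):
        load_ruleset(cfg)


def test_partial_vocabulary_rejected(tmp_path):
    # a user-supplied vocabulary must cover every cancer/modality combination
    cfg = tmp_path / "partial.yaml"
    cfg.write_text("label_vocabulary:\n  breast/MG:\n    1: {name: Benign, class: benign}\n")
    with pytest.raises(RulesetError, match="prostate/MR"):
        load_ruleset(cfg)


def test_bad_threshold_order_rejected(tmp_path):
    cfg = tmp_path / "bad.yaml"
    cfg.write_text("dedup: {high: 10.0, normal: 0.1}\n")
    with pytest.raises(RulesetError, match="thresholds"):
        load_ruleset(cfg)


def test_require_vocabulary():
    rs = default_ruleset()
    assert require_vocabulary(rs, "breast", "MG")[1].klass == "benign"
    rs.label_vocabulary.pop(("prostate", "MR"))
    with pytest.raises(RulesetError):
        require_vocabulary(rs, "prostate", "MR")


def test_merge_preserves_defaults(tmp_path):
    cfg = tmp_path / "partial.yaml"
    cfg.write_text("dominance_share: 0.9\n")
    rs = load_ruleset(cfg)
    assert rs.dominance_share == 0.9
    assert rs.mandatory_fields == default_ruleset().mandatory_fields


@given(st.lists(st.integers(min_value=-50, max_value=200), min_size=1))
def test_integer_rule_range_property(values):
    rule = FieldRule(type="integer", min=0, max=120)
    for v in values:
        assert rule.is_valid(str(v)) == (0 <= v <= 120)
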