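"""Generator: determinism, exact composition and manifest bookkeeping."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pytest

from cimqc import GenerationError, GenerationParams, generate_repository
from cimqc.synthetic_repo import _exact_count, make_phantom_image, make_report_image


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_same_seed_byte_identical(tmp_path):
    params = GenerationParams(seed=11, providers=1, patients_per_provider=4,
                              with_annotations=True,
                              rates={"missing_mandatory": 0.25,
                                     "retained_sex_tag": 0.125})
    _, m1 = generate_repository(params, tmp_path / "a")
    _, m2 = generate_repository(params, tmp_path / "b")
    assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")
    assert m1.to_dict() == m2.to_dict()


def test_different_seed_differs(tmp_path):
    base = dict(providers=1, patients_per_provider=4, with_annotations=False)
    generate_repository(GenerationParams(seed=1, **base), tmp_path / "a")
    generate_repository(GenerationParams(seed=2, **base), tmp_path / "b")
    assert _tree_digest(tmp_path / "a") != _tree_digest(tmp_path / "b")


def test_counts_and_expected_consistent(small_repo):
    root, manifest = small_repo
    saved = json.loads((root / "ground_truth_manifest.json").read_text())
    assert saved["counts"] == manifest.counts
    assert saved["expected"] == manifest.expected
    # one defect entry per planted defect
    assert len(saved["defects"]) == len(manifest.defects)


def test_unknown_defect_class_rejected(tmp_path):
    with pytest.raises(GenerationError):
        generate_repository(GenerationParams(rates={"bogus": 0.1}),
                            tmp_path / "x")


def test_overflowing_rates_rejected(tmp_path):
    # missing + crosslink cannot exceed the patient universe
    with pytest.raises(GenerationError):
        generate_repository(GenerationParams(
            providers=1, patients_per_provider=4,
            rates={"missing_mandatory": 0.75, "crosslink_break": 0.75}),
            tmp_path / "x")


def test_exact_count_is_exact_on_divisible_universes():
    assert _exact_count(0.1, 200) == 20
    assert _exact_count(0.25, 1800) == 450
    assert _exact_count(0.5, 400) == 200


def test_image_generators_are_separable_by_level_richness():
    import numpy as np
    rng = np.random.default_rng(0)
    phantom = make_phantom_image(rng, 32)
    report = make_report_image(rng, 32)
    def levels(a):
        lo, hi = a.min(), a.max()
        scaled = np.rint((a - lo) * (255.0 / (hi - lo)))
        return np.unique(scaled).size
    assert levels(phantom) > 64
    assert levels(report) <= 64


def test_prostate_patients_are_male(small_repo, small_table):
    _, manifest = small_repo
    invalid_sex = {r.split("/")[0] for r in manifest.defect_records("invalid_value")
                   if r.endswith("/sex")}
    for rec in small_table.records():
        if rec["cancer_type"] == "prostate" and \
                rec["patient_id"] not in invalid_sex:
            assert rec["sex"] == "M"


def test_cancer_mix_exact_on_multiples_of_20(small_table):
    counts = {}
    for rec in small_table.records():
        counts[rec["cancer_type"]] = counts.get(rec["cancer_type"], 0) + 1
    assert counts == {"breast": 5, "lung": 5, "colorectal": 5, "prostate": 5}
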