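"""Duplicate detection: UID screen, pixel MSE and scan semantics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cimqc import (intra_patient_scan, inter_patient_scan, pixel_mse,
                   uid_screen)
from cimqc.clinical_metrics import ratio_percentage
from cimqc.imaging_dedup import (SeriesPairComparison, prepare_image,
                                 similarity_percentage)


def test_pixel_mse_identity_and_symmetry():
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 4096, (32, 32))
    b = rng.uniform(0, 4096, (32, 32))
    assert pixel_mse(a, a) == 0.0
    assert pixel_mse(a, b) == pytest.approx(pixel_mse(b, a))
    assert pixel_mse(a, b) > 0.1


def test_mse_invariant_to_affine_intensity_rescale():
    # min-max normalization makes window/level shifts invisible
    rng = np.random.default_rng(1)
    a = rng.uniform(0, 100, (64, 64))
    assert pixel_mse(a, 3.5 * a + 40.0) == pytest.approx(0.0, abs=1e-9)


def test_mse_resamples_mixed_sizes():
    rng = np.random.default_rng(2)
    a = rng.uniform(0, 255, (128, 128)).astype(np.float64)
    small = np.asarray(prepare_image(a, 64))
    assert small.shape == (64, 64)
    assert pixel_mse(a, a) == 0.0


@given(hnp.arrays(np.float64, (16, 16),
                  elements=st.floats(0, 1000, allow_nan=False)))
def test_mse_nonnegative_and_constant_safe(arr):
    assert pixel_mse(arr, arr) == 0.0
    assert pixel_mse(arr, np.zeros((16, 16))) >= 0.0


def test_uid_screen_finds_planted_duplicates(small_repo, small_index):
    _, manifest = small_repo
    groups = uid_screen(small_index)
    grouped_series = {m["path"].rsplit("/", 1)[0]
                      for g in groups for m in g.to_dict()["members"]}
    root = str(small_repo[0])
    expected = set()
    for pair in manifest.duplicate_pairs:
        expected.add(f"{root}/{pair['source']}")
        expected.add(f"{root}/{pair['copy']}")
    assert grouped_series == expected


def test_pixel_scan_flags_exactly_planted_pairs(small_repo, small_index,
                                                ruleset):
    root, manifest = small_repo
    flagged = set()
    for prov in sorted(small_index.providers):
        provider = small_index.providers[prov]
        for pid in sorted(provider.patients):
            f = intra_patient_scan(provider.patients[pid], "high", ruleset)
            flagged |= {frozenset((str(p.series_a), str(p.series_b)))
                        for p in f.flagged_pairs}
        f = inter_patient_scan(provider, "high", ruleset)
        flagged |= {frozenset((str(p.series_a), str(p.series_b)))
                    for p in f.flagged_pairs}
    expected = {frozenset((f"{root}/{p['source']}", f"{root}/{p['copy']}"))
                for p in manifest.duplicate_pairs}
    assert expected <= flagged
    # nothing outside the planted pairs is a byte-identical duplicate
    assert flagged == expected


def test_grade_monotonicity(small_index, ruleset):
    """Every pair flagged at grade high is flagged at grade normal."""
    prov = sorted(small_index.providers)[0]
    provider = small_index.providers[prov]
    for pid in sorted(provider.patients):
        patient = provider.patients[pid]
        hi = intra_patient_scan(patient, "high", ruleset)
        lo = intra_patient_scan(patient, "normal", ruleset)
        hi_pairs = {(str(p.series_a), str(p.series_b)) for p in hi.flagged_pairs}
        lo_pairs = {(str(p.series_a), str(p.series_b)) for p in lo.flagged_pairs}
        assert hi_pairs <= lo_pairs


def test_similarity_percentage_reconstructions():
    pair = SeriesPairComparison(series_a=None, series_b=None, modality="CT",
                                timepoint_a=1, timepoint_b=2,
                                n_comparisons=119,
                                flagged=[(None, None, 0.0)] * 110)
    assert similarity_percentage(pair) == 92.44
    pair2 = SeriesPairComparison(series_a=None, series_b=None, modality="CT",
                                 timepoint_a=1, timepoint_b=1,
                                 n_comparisons=105,
                                 flagged=[(None, None, 0.0)] * 4)
    assert similarity_percentage(pair2) == 3.81
    empty = SeriesPairComparison(series_a=None, series_b=None, modality="CT",
                                 timepoint_a=None, timepoint_b=None,
                                 n_comparisons=0)
    assert similarity_percentage(empty) is None


def test_timepoint_gap():
    pair = SeriesPairComparison(series_a=None, series_b=None, modality="CT",
                                timepoint_a=1, timepoint_b=3, n_comparisons=1)
    assert pair.timepoint_gap == 2
    pair = SeriesPairComparison(series_a=None, series_b=None, modality="CT",
                                timepoint_a=None, timepoint_b=3, n_comparisons=1)
    assert pair.timepoint_gap is None


def test_scan_restricted_to_same_modality(small_index, ruleset):
    for prov in sorted(small_index.providers):
        provider = small_index.providers[prov]
        f = inter_patient_scan(provider, "high", ruleset)
        for p in f.pairs:
            assert p.modality  # pairs carry one shared modality by construction
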