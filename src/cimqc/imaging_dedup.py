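"""Two-level duplicate and similarity detection.

Level 1 is a rapid screen on the media-storage SOP instance UID, tag
(0002,0003): any UID shared by two or more files forms a candidate group.
Groups spanning different modalities are annotated as likely
de-identification artifacts (the tag was rewritten with colliding values)
rather than confirmed duplicates.

Level 2 is pairwise pixel comparison: every slice is resampled to a common
64x64 grid by bilinear interpolation, min-max scaled to [0, 255] per image,
and compared by mean squared error.  A series pair is flagged when at least
one slice pair falls at or under the grade threshold (``high`` = 0.1 by
default; ``normal`` is a configurable laxer threshold).  The
similarity-percentage score of a pair is the share of flagged slice
comparisons among all slice comparisons performed.  Intra-patient scans
compare series within one patient; inter-patient scans compare series across
the patients of one provider.  Pixel comparison is restricted to
same-modality pairs; findings are advisory flags for curation, never
deletions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
from PIL import Image

from .clinical_metrics import ratio_percentage
from .repo_model import PatientEntry, ProviderEntry, RepositoryIndex, SeriesRecord
from .rules_config import DedupConfig, QualityRuleSet

logger = logging.getLogger(__name__)


@dataclass
class DuplicateCandidateGroup:
    uid: str
    #: (path, patient_id, timepoint, modality)
    members: list[tuple[Path, str, Optional[int], str]]
    cross_modality: bool = False

    def to_dict(self) -> dict:
        return {
            "uid": self.uid,
            "cross_modality": self.cross_modality,
            "members": [{"path": str(p), "patient": pid, "timepoint": tp,
                         "modality": m} for p, pid, tp, m in self.members],
        }


def uid_screen(index: RepositoryIndex) -> list[DuplicateCandidateGroup]:
    """Group files sharing a media-storage SOP instance UID."""
    by_uid: dict[str, list[tuple[Path, str, Optional[int], str]]] = {}
    for series, inst in index.iter_instances():
        if inst.media_storage_sop_uid is None:
            continue
        by_uid.setdefault(inst.media_storage_sop_uid, []).append(
            (inst.path, series.patient_id, series.timepoint, series.modality))
    groups = []
    for uid in sorted(by_uid):
        members = by_uid[uid]
        if len(members) < 2:
            continue
        modalities = {m for _, _, _, m in members}
        groups.append(DuplicateCandidateGroup(
            uid=uid, members=members, cross_modality=len(modalities) > 1))
    return groups


# ---------------------------------------------------------------------------
# Pixel similarity


def _minmax_255(arr: np.ndarray) -> np.ndarray:
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        # constant image: scaled to all-zeros by convention
        return np.zeros_like(arr)
    return (arr - lo) * (255.0 / (hi - lo))


def prepare_image(arr: np.ndarray, size: int = 64) -> np.ndarray:
    """Resample to ``size`` x ``size`` (bilinear) then min-max scale to [0, 255]."""
    arr = np.asarray(arr, dtype=np.float64)
    if arr.shape != (size, size):
        im = Image.fromarray(arr.astype(np.float32), mode="F")
        arr = np.asarray(im.resize((size, size), Image.BILINEAR), dtype=np.float64)
    return _minmax_255(arr)


def pixel_mse(image_a: np.ndarray, image_b: np.ndarray, size: int = 64) -> float:
    """Mean squared error between two intensity images on the common grid.

    Symmetric; 0.0 for identical inputs.
    """
    a = prepare_image(image_a, size)
    b = prepare_image(image_b, size)
    return float(np.mean((a - b) ** 2))


def load_slice_pixels(path: Path) -> np.ndarray:
    """Read one DICOM slice as float intensities with rescale applied."""
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    return arr * slope + intercept


class _SliceCache:
    """Prepared (resampled + scaled) slices keyed by file path."""

    def __init__(self, size: int):
        self.size = size
        self._cache: dict[Path, Optional[np.ndarray]] = {}

    def get(self, path: Path) -> Optional[np.ndarray]:
        if path not in self._cache:
            try:
                self._cache[path] = prepare_image(load_slice_pixels(path), self.size)
            except Exception as exc:
                logger.warning("unreadable pixel data in %s: %s", path, exc)
                self._cache[path] = None
        return self._cache[path]


@dataclass
class SeriesPairComparison:
    series_a: Path
    series_b: Path
    modality: str
    timepoint_a: Optional[int]
    timepoint_b: Optional[int]
    n_comparisons: int
    flagged: list[tuple[Path, Path, float]] = field(default_factory=list)
    non_assessed: int = 0

    @property
    def is_flagged(self) -> bool:
        return bool(self.flagged)

    @property
    def similarity_percentage(self) -> Optional[float]:
        return similarity_percentage(self)

    @property
    def timepoint_gap(self) -> Optional[int]:
        if self.timepoint_a is None or self.timepoint_b is None:
            return None
        return abs(self.timepoint_a - self.timepoint_b)

    def to_dict(self) -> dict:
        return {
            "series_a": str(self.series_a), "series_b": str(self.series_b),
            "modality": self.modality, "timepoint_gap": self.timepoint_gap,
            "n_comparisons": self.n_comparisons,
            "n_flagged": len(self.flagged),
            "similarity_percentage": self.similarity_percentage,
        }


@dataclass
class SimilarityFindings:
    scope: str           # intra | inter
    grade: str           # high | normal
    threshold: float
    pairs: list[SeriesPairComparison] = field(default_factory=list)

    @property
    def comparisons_performed(self) -> int:
        return len(self.pairs)

    @property
    def flagged_pairs(self) -> list[SeriesPairComparison]:
        return [p for p in self.pairs if p.is_flagged]

    def by_modality(self) -> dict[str, tuple[int, int]]:
        """modality -> (series-pair comparisons, flagged series pairs)."""
        out: dict[str, tuple[int, int]] = {}
        for p in self.pairs:
            total, flagged = out.get(p.modality, (0, 0))
            out[p.modality] = (total + 1, flagged + (1 if p.is_flagged else 0))
        return out

    def to_dict(self) -> dict:
        return {
            "scope": self.scope, "grade": self.grade, "threshold": self.threshold,
            "comparisons": self.comparisons_performed,
            "flagged": len(self.flagged_pairs),
            "by_modality": {m: {"comparisons": c, "flagged": f}
                            for m, (c, f) in sorted(self.by_modality().items())},
            "by_timepoint_gap": {str(k): {"comparisons": c, "flagged": f}
                                 for k, (c, f) in
                                 sorted(stratify_by_timepoint_gap(self).items(),
                                        key=lambda kv: str(kv[0]))},
            "pairs": [p.to_dict() for p in self.flagged_pairs],
        }


def compare_series_pair(series_a: SeriesRecord, series_b: SeriesRecord,
                        threshold: float, cache: _SliceCache,
                        cap: int = 200) -> SeriesPairComparison:
    """Slice-wise comparison of two same-modality series.

    All cross slice pairs are compared when both series are at or under the
    cap; longer series are aligned by slice index to bound the work.
    """
    paths_a = [i.path for i in series_a.instances]
    paths_b = [i.path for i in series_b.instances]
    if len(paths_a) <= cap and len(paths_b) <= cap:
        pairs = [(pa, pb) for pa in paths_a for pb in paths_b]
    else:
        pairs = list(zip(paths_a, paths_b))
    result = SeriesPairComparison(
        series_a=series_a.path, series_b=series_b.path,
        modality=series_a.modality,
        timepoint_a=series_a.timepoint, timepoint_b=series_b.timepoint,
        n_comparisons=0)
    for pa, pb in pairs:
        a, b = cache.get(pa), cache.get(pb)
        if a is None or b is None:
            result.non_assessed += 1
            continue
        result.n_comparisons += 1
        mse = float(np.mean((a - b) ** 2))
        if mse <= threshold:
            result.flagged.append((pa, pb, mse))
    return result


def _scan(series_pairs: list[tuple[SeriesRecord, SeriesRecord]], scope: str,
          grade: str, dedup: DedupConfig) -> SimilarityFindings:
    threshold = dedup.threshold(grade)
    cache = _SliceCache(dedup.resample_size)
    findings = SimilarityFindings(scope=scope, grade=grade, threshold=threshold)
    for sa, sb in series_pairs:
        findings.pairs.append(compare_series_pair(
            sa, sb, threshold, cache, dedup.slice_pair_cap))
    return findings


def intra_patient_scan(patient: PatientEntry, grade: str,
                       ruleset: QualityRuleSet) -> SimilarityFindings:
    """Compare all unordered same-modality series pairs within one patient."""
    series = list(patient.iter_series())
    pairs = [(series[i], series[j])
             for i in range(len(series)) for j in range(i + 1, len(series))
             if series[i].modality == series[j].modality]
    return _scan(pairs, "intra", grade, ruleset.dedup)


def inter_patient_scan(provider: ProviderEntry, grade: str,
                       ruleset: QualityRuleSet) -> SimilarityFindings:
    """Compare same-modality series pairs across patients of one provider."""
    by_patient = [list(provider.patients[pid].iter_series())
                  for pid in sorted(provider.patients)]
    pairs = []
    for i in range(len(by_patient)):
        for j in range(i + 1, len(by_patient)):
            for sa in by_patient[i]:
                for sb in by_patient[j]:
                    if sa.modality == sb.modality:
                        pairs.append((sa, sb))
    return _scan(pairs, "inter", grade, ruleset.dedup)


def similarity_percentage(pair: SeriesPairComparison) -> Optional[float]:
    """Flagged slice comparisons over total slice comparisons, 2 decimals."""
    return ratio_percentage(len(pair.flagged), pair.n_comparisons)


def stratify_by_timepoint_gap(findings: SimilarityFindings,
                              ) -> dict[object, tuple[int, int]]:
    """gap (|tA - tB| or 'unknown') -> (comparisons, flagged series pairs)."""
    table: dict[object, tuple[int, int]] = {}
    for p in findings.pairs:
        gap = p.timepoint_gap if p.timepoint_gap is not None else "unknown"
        total, flagged = table.get(gap, (0, 0))
        table[gap] = (total + 1, flagged + (1 if p.is_flagged else 0))
    return table
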