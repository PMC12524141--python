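"""Synthetic repository generator with a ground-truth defect manifest.

Emits a complete repository — minimal part-10 DICOM series, NIfTI annotation
masks and one clinical template CSV per cancer type — with every defect class
injected at configured rates into disjoint records, plus a manifest recording
each injected defect and the closed-form expected value of every count-based
metric.  The manifest is the oracle for all parameter-recovery tests.

Defect classes and the record universe each draws from:

================  ==========================================================
missing_mandatory   patients (a mandatory free-text field blanked)
invalid_value       inserted values in constrained fields ("3" for stage III,
                    out-of-range age, miscased codes, ...)
crosslink_break     per-patient cross-link evaluations (biopsy set to
                    "No Biopsy" while biomarkers stay populated)
modality_mismatch   provided modality instances per (patient, timepoint)
                    (declared series count bumped)
naming_violation    provided modality instances (directory renamed e.g.
                    ``ct_scan``)
duplicate_series_*  series (byte-copied within a patient / re-identified
                    copies across patients)
mask_roi_mismatch   masks (in-plane dims halved)
mask_slice_mismatch masks (slice count offset)
empty_mask          masks (all-zero)
unknown_label       masks (label code outside the vocabulary)
retained_sex_tag    DICOM files (PatientSex kept)
retained_age_tag    DICOM files (PatientAge kept)
date_hash_wrong_id  DICOM files (dates hashed with a different patient id)
burnt_in_report     DICOM files (pixels replaced by a rendered report page)
================  ==========================================================

Determinism: the seed fully determines the output; the same parameters write
byte-identical trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from datetime import timedelta
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .clinical_metrics import ratio_percentage
from .deid_audit import expected_offset
from .rules_config import DeidProfile

DEFECT_CLASSES = (
    "missing_mandatory", "invalid_value", "crosslink_break",
    "modality_mismatch", "naming_violation",
    "duplicate_series_intra", "duplicate_series_inter",
    "mask_roi_mismatch", "mask_slice_mismatch", "empty_mask", "unknown_label",
    "retained_sex_tag", "retained_age_tag", "date_hash_wrong_id",
    "burnt_in_report",
)

_SOP_CLASS = {
    "CT": "1.2.840.10008.5.1.4.1.1.2",
    "FUSCT": "1.2.840.10008.5.1.4.1.1.2",
    "MR": "1.2.840.10008.5.1.4.1.1.4",
    "MG": "1.2.840.10008.5.1.4.1.1.1.2",
    "US": "1.2.840.10008.5.1.4.1.1.6.1",
    "PT": "1.2.840.10008.5.1.4.1.1.128",
    "FUSPT": "1.2.840.10008.5.1.4.1.1.128",
    "XRAY": "1.2.840.10008.5.1.4.1.1.1",
}
_DICOM_MODALITY = {"FUSCT": "CT", "FUSPT": "PT", "XRAY": "CR"}

#: fields validity assesses that no other defect class touches
SAFE_INVALID_FIELDS = ("sex", "age", "grade", "stage", "histological_type",
                       "er_status", "pr_status")
#: value written when a field is made invalid
INVALID_TOKENS = {
    "sex": "male",
    "age": "200",
    "grade": "G2",
    "stage": "3",               # "3" instead of "III"
    "histological_type": "unknown-type",
    "er_status": "positiv",
    "pr_status": "Positive?",
}
_HISTOLOGY = {
    "breast": ["IDC", "ILC", "DCIS"],
    "lung": ["Adenocarcinoma", "Squamous", "Small-cell"],
    "colorectal": ["Adenocarcinoma", "Squamous"],
    "prostate": ["Adenocarcinoma"],
}
_MANUFACTURERS = ["GE", "Siemens", "Philips"]
_THICKNESS = {"CT": "3.0", "FUSCT": "3.27", "PT": "3.27", "FUSPT": "3.27",
              "MR": "3.0", "MG": "1.0", "US": "1.0", "XRAY": "1.0"}


class GenerationError(Exception):
    """Impossible composition: defect rates exceed record counts."""


@dataclass
class GenerationParams:
    seed: int = 1
    providers: int = 1
    patients_per_provider: int = 10
    cancer_mix: dict[str, float] = dc_field(default_factory=lambda: {
        "breast": 0.25, "lung": 0.25, "colorectal": 0.25, "prostate": 0.25})
    #: timepoint ordinal -> modality codes provided there
    modalities_per_timepoint: dict[int, list[str]] = dc_field(
        default_factory=lambda: {1: ["CT"], 2: ["CT"]})
    slices_per_series: int = 2
    image_size: int = 32
    with_annotations: bool = False
    rates: dict[str, float] = dc_field(default_factory=dict)
    #: provider -> variable -> ordered (class value, count) pairs;
    #: variables: sex, age, grade, histological_type
    composition: dict[str, dict[str, list[tuple[str, int]]]] = dc_field(
        default_factory=dict)
    deid_profile: DeidProfile = dc_field(default_factory=DeidProfile)

    def validate(self) -> None:
        for name, rate in self.rates.items():
            if name not in DEFECT_CLASSES:
                raise GenerationError(f"unknown defect class {name!r}")
            if not 0.0 <= rate <= 1.0:
                raise GenerationError(f"rate {name}={rate} outside [0, 1]")


@dataclass
class GroundTruthManifest:
    params_seed: int
    counts: dict = dc_field(default_factory=dict)
    defects: list[dict] = dc_field(default_factory=list)
    expected: dict = dc_field(default_factory=dict)
    duplicate_pairs: list[dict] = dc_field(default_factory=list)

    def defect_records(self, klass: str) -> list[str]:
        return [d["record"] for d in self.defects if d["class"] == klass]

    def to_dict(self) -> dict:
        return {"seed": self.params_seed, "counts": self.counts,
                "expected": self.expected, "defects": self.defects,
                "duplicate_pairs": self.duplicate_pairs}

    def save(self, path: Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Procedural images


def make_phantom_image(rng: np.random.Generator, size: int = 32) -> np.ndarray:
    """Smooth elliptical phantom with a full-range gradient plus noise.

    The intensity spectrum is rich (far more than 64 distinct 8-bit levels),
    so the report classifier reads it as an organ.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = size / 2 + rng.uniform(-size / 8, size / 8)
    cx = size / 2 + rng.uniform(-size / 8, size / 8)
    ry = size * rng.uniform(0.30, 0.45)
    rx = size * rng.uniform(0.30, 0.45)
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    body = np.clip(1.0 - r2, 0.0, 1.0) * 180.0
    gradient = 40.0 * (xx / size)
    noise = rng.normal(0.0, 8.0, (size, size))
    img = np.clip(body + gradient + np.abs(noise), 0, 255)
    return img.astype(np.uint8)


def make_report_image(rng: np.random.Generator, size: int = 32) -> np.ndarray:
    """Text-like bimodal raster: white page with black glyph blocks."""
    img = np.full((size, size), 255, dtype=np.uint8)
    n_lines = max(2, size // 8)
    for line in range(n_lines):
        y0 = 2 + line * (size - 4) // n_lines
        height = max(1, size // 16)
        x = 2
        while x < size - 4:
            width = int(rng.integers(1, max(2, size // 10)))
            if rng.random() < 0.6:
                img[y0:y0 + height, x:x + width] = 0
            x += width + 1
    return img


def make_noise_image(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """Independent uniform-noise image; pairwise MSE far above any threshold."""
    return rng.integers(0, 256, size=(size, size), dtype=np.uint8).astype(np.uint8)


# ---------------------------------------------------------------------------
# DICOM writing


class _UidFactory:
    def __init__(self, seed: int):
        self.prefix = f"1.2.826.0.1.3680043.9999.{seed % (2**31)}"
        self.counter = 0

    def next(self) -> str:
        self.counter += 1
        return f"{self.prefix}.{self.counter}"


def write_dicom_instance(path: Path, pixels: np.ndarray, *, uid: str,
                         modality_code: str, patient_id: str, study_date: str,
                         manufacturer: str, slice_thickness: str,
                         pixel_spacing: tuple[str, str] = ("0.98", "0.98"),
                         field_strength: Optional[str] = None,
                         kernel: Optional[str] = None,
                         patient_sex: Optional[str] = None,
                         patient_age: Optional[str] = None) -> None:
    sop_class = _SOP_CLASS.get(modality_code, _SOP_CLASS["CT"])
    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = sop_class
    fm.MediaStorageSOPInstanceUID = uid
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    fm.ImplementationClassUID = "1.2.826.0.1.3680043.9999.0.1"
    fm.ImplementationVersionName = "CIMQC_SYNTH"
    ds = FileDataset(str(path), {}, file_meta=fm, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = uid
    ds.Modality = _DICOM_MODALITY.get(modality_code, modality_code)
    ds.PatientID = patient_id
    ds.StudyDate = study_date
    ds.SeriesDate = study_date
    ds.Manufacturer = manufacturer
    ds.SliceThickness = slice_thickness
    ds.PixelSpacing = list(pixel_spacing)
    if field_strength is not None:
        ds.MagneticFieldStrength = field_strength
    if kernel is not None:
        ds.ConvolutionKernel = kernel
    if patient_sex is not None:
        ds.PatientSex = patient_sex
    if patient_age is not None:
        ds.PatientAge = patient_age
    arr = np.ascontiguousarray(pixels.astype(np.uint8))
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _write_mask(path: Path, shape: tuple[int, int, int], label: int,
                rng: np.random.Generator) -> None:
    data = np.zeros(shape, dtype=np.int16)
    if label > 0:
        r, c, s = shape
        data[r // 4: max(r // 4 + 2, r // 2),
             c // 4: max(c // 4 + 2, c // 2), :] = label
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))


# ---------------------------------------------------------------------------
# Plan


@dataclass
class _SeriesPlan:
    provider: str
    patient: str
    timepoint: int
    modality: str
    series_id: str
    n_slices: int
    duplicate_of: Optional["_SeriesPlan"] = None
    inter: bool = False
    mask_label: int = 0
    mask_shape: Optional[tuple[int, int, int]] = None
    naming_violation: bool = False

    def mod_dirname(self) -> str:
        return self.modality.lower() + "_scan" if self.naming_violation \
            else self.modality


def _allocate(rng: np.random.Generator, universe: list, counts: dict[str, int],
              what: str) -> dict[str, list]:
    """Partition a shuffled universe into disjoint defect groups."""
    total = sum(counts.values())
    if total > len(universe):
        raise GenerationError(
            f"defect counts {counts} exceed the {len(universe)} available {what}")
    order = list(universe)
    rng.shuffle(order)
    out, cursor = {}, 0
    for name, k in counts.items():
        out[name] = order[cursor:cursor + k]
        cursor += k
    return out


def _exact_count(rate: float, n: int) -> int:
    return int(round(rate * n))


def generate_repository(params: GenerationParams,
                        out_dir: Path) -> tuple[Path, GroundTruthManifest]:
    """Write a synthetic repository under ``out_dir`` and return its manifest."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    uids = _UidFactory(params.seed)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rate = {name: params.rates.get(name, 0.0) for name in DEFECT_CLASSES}
    manifest = GroundTruthManifest(params_seed=params.seed)

    providers = [f"DP{i + 1}" for i in range(params.providers)]
    cancers = sorted(params.cancer_mix)
    weights = np.array([params.cancer_mix[c] for c in cancers], dtype=float)
    weights = weights / weights.sum()

    # -- patient plans ------------------------------------------------------
    patients: list[dict] = []
    for pi, prov in enumerate(providers):
        comp = params.composition.get(prov, {})
        comp_values = {var: [cls for cls, cnt in pairs for _ in range(cnt)]
                       for var, pairs in comp.items()}
        for j in range(params.patients_per_provider):
            idx = pi * params.patients_per_provider + j
            cancer = cancers[int(np.searchsorted(
                np.cumsum(weights), ((idx % 20) + 0.5) / 20.0))]
            pid = f"{prov}-P{idx:04d}"
            hist = _HISTOLOGY[cancer]
            rec = {
                "patient_id": pid, "provider_id": prov, "cancer_type": cancer,
                "sex": "M" if cancer == "prostate" else ("M", "F")[idx % 2],
                "age": str(int(rng.integers(35, 86))),
                "grade": str(1 + idx % 3),
                "histological_type": hist[idx % len(hist)],
                "stage": ["I", "II", "III", "IV"][idx % 4],
                "biopsy": "Biopsy",
                "er_status": ("positive", "negative")[idx % 2],
                "pr_status": ("positive", "negative")[(idx + 1) % 2],
                "her2_status": ("positive", "negative")[idx % 2],
                "primary_diagnosis_text": f"routine diagnostic workup case {idx}",
            }
            for var, values in comp_values.items():
                if j < len(values):
                    rec[var] = values[j]
            patients.append(rec)
    n_patients = len(patients)

    # -- series plans -------------------------------------------------------
    series_plans: list[_SeriesPlan] = []
    for rec in patients:
        for tp, modalities in sorted(params.modalities_per_timepoint.items()):
            for mod in modalities:
                series_plans.append(_SeriesPlan(
                    provider=rec["provider_id"], patient=rec["patient_id"],
                    timepoint=tp, modality=mod,
                    series_id=f"S{len(series_plans):05d}",
                    n_slices=params.slices_per_series))

    # duplicates ------------------------------------------------------------
    base_series = list(series_plans)
    k_dup_intra = _exact_count(rate["duplicate_series_intra"], len(base_series))
    k_dup_inter = _exact_count(rate["duplicate_series_inter"], len(base_series))
    dup_alloc = _allocate(rng, base_series,
                          {"intra": k_dup_intra, "inter": k_dup_inter}, "series")
    patients_by_provider: dict[str, list[str]] = {}
    for rec in patients:
        patients_by_provider.setdefault(rec["provider_id"], []).append(
            rec["patient_id"])
    for src in dup_alloc["intra"]:
        series_plans.append(_SeriesPlan(
            provider=src.provider, patient=src.patient, timepoint=src.timepoint,
            modality=src.modality, series_id=f"S{len(series_plans):05d}",
            n_slices=src.n_slices, duplicate_of=src))
    for src in dup_alloc["inter"]:
        peers = [p for p in patients_by_provider[src.provider] if p != src.patient]
        if not peers:
            raise GenerationError(
                "duplicate_series_inter needs at least two patients per provider")
        target = peers[int(rng.integers(len(peers)))]
        series_plans.append(_SeriesPlan(
            provider=src.provider, patient=target, timepoint=src.timepoint,
            modality=src.modality, series_id=f"S{len(series_plans):05d}",
            n_slices=src.n_slices, duplicate_of=src, inter=True))

    # integrity-record defects ----------------------------------------------
    slots = sorted({(s.provider, s.patient, s.timepoint, s.modality)
                    for s in series_plans})
    k_mm = _exact_count(rate["modality_mismatch"], len(slots))
    k_nv = _exact_count(rate["naming_violation"], len(slots))
    slot_alloc = _allocate(rng, slots, {"mismatch": k_mm, "naming": k_nv},
                           "modality records")
    mismatch_slots = set(slot_alloc["mismatch"])
    naming_slots = set(slot_alloc["naming"])
    for s in series_plans:
        if (s.provider, s.patient, s.timepoint, s.modality) in naming_slots:
            s.naming_violation = True

    # clinical defects -------------------------------------------------------
    k_miss = _exact_count(rate["missing_mandatory"], n_patients)
    k_break = _exact_count(rate["crosslink_break"], n_patients)
    pat_alloc = _allocate(rng, list(range(n_patients)),
                          {"missing": k_miss, "break": k_break}, "patients")
    for i in pat_alloc["missing"]:
        patients[i]["primary_diagnosis_text"] = ""
        manifest.defects.append({"class": "missing_mandatory",
                                 "record": patients[i]["patient_id"]})
    for i in pat_alloc["break"]:
        patients[i]["biopsy"] = "No Biopsy"  # biomarkers stay populated
        manifest.defects.append({"class": "crosslink_break",
                                 "record": patients[i]["patient_id"]})

    n_assessed_values = 9 * n_patients  # constrained fields per template row
    k_invalid = _exact_count(rate["invalid_value"], n_assessed_values)
    cells = [(i, f) for i in range(n_patients) for f in SAFE_INVALID_FIELDS]
    cell_alloc = _allocate(rng, cells, {"invalid": k_invalid},
                           "injectable values")
    for i, fname in cell_alloc["invalid"]:
        patients[i][fname] = INVALID_TOKENS[fname]
        manifest.defects.append({
            "class": "invalid_value",
            "record": f"{patients[i]['patient_id']}/{fname}"})

    # declarations (built to match provisions, then defects applied) ---------
    provided: dict[tuple[str, int], dict[str, int]] = {}
    for s in series_plans:
        key = (s.patient, s.timepoint)
        provided.setdefault(key, {})
        provided[key][s.modality] = provided[key].get(s.modality, 0) + 1
    for rec in patients:
        for tp in sorted(params.modalities_per_timepoint):
            decl = dict(provided.get((rec["patient_id"], tp), {}))
            slot_mods = sorted(decl)
            for mod in slot_mods:
                if (rec["provider_id"], rec["patient_id"], tp, mod) in mismatch_slots:
                    decl[mod] += 1
                    manifest.defects.append({
                        "class": "modality_mismatch",
                        "record": f"{rec['patient_id']}/T{tp}/{mod}"})
            rec[f"modalities_t{tp}"] = ";".join(
                f"{m}:{decl[m]}" for m in sorted(decl))
    for slot in sorted(naming_slots):
        manifest.defects.append({
            "class": "naming_violation",
            "record": f"{slot[1]}/T{slot[2]}/{slot[3]}"})

    # file-level de-identification defects -----------------------------------
    file_keys: list[tuple[str, int]] = []  # (series_id, slice index)
    eligible: list[tuple[str, int]] = []
    dup_sources = {s.duplicate_of.series_id for s in series_plans
                   if s.duplicate_of is not None}
    for s in series_plans:
        for k in range(s.n_slices):
            file_keys.append((s.series_id, k))
            # byte-copied duplicates must stay identical to their source
            if s.duplicate_of is None and s.series_id not in dup_sources:
                eligible.append((s.series_id, k))
    n_files = len(file_keys)
    deid_counts = {name: _exact_count(rate[name], n_files)
                   for name in ("retained_sex_tag", "retained_age_tag",
                                "date_hash_wrong_id", "burnt_in_report")}
    deid_alloc = _allocate(rng, eligible, deid_counts, "eligible DICOM files")
    deid_of_file: dict[tuple[str, int], str] = {}
    for name, keys in deid_alloc.items():
        for key in keys:
            deid_of_file[key] = name

    # mask defects ------------------------------------------------------------
    mask_series = [s for s in series_plans if s.duplicate_of is None] \
        if params.with_annotations else []
    if params.with_annotations:
        mask_counts = {name: _exact_count(rate[name], len(mask_series))
                       for name in ("mask_roi_mismatch", "mask_slice_mismatch",
                                    "empty_mask", "unknown_label")}
        mask_alloc = _allocate(rng, mask_series, mask_counts, "masks")
        for s in mask_series:
            s.mask_label = 3  # malignant by the default vocabulary
            s.mask_shape = (params.image_size, params.image_size, s.n_slices)
        for s in mask_alloc["mask_roi_mismatch"]:
            s.mask_shape = (params.image_size // 2, params.image_size // 2,
                            s.n_slices)
        for s in mask_alloc["mask_slice_mismatch"]:
            s.mask_shape = (params.image_size, params.image_size, s.n_slices + 3)
        for s in mask_alloc["empty_mask"]:
            s.mask_label = 0
        for s in mask_alloc["unknown_label"]:
            s.mask_label = 9
        for name, selected in mask_alloc.items():
            for s in selected:
                manifest.defects.append({
                    "class": name,
                    "record": f"{s.patient}/T{s.timepoint}/{s.modality}/"
                              f"{s.series_id}"})

    # -- write ----------------------------------------------------------------
    cancer_of_patient = {rec["patient_id"]: rec["cancer_type"] for rec in patients}
    profile = params.deid_profile
    anchor = profile.anchor()
    slice_images: dict[tuple[str, int], np.ndarray] = {}
    slice_uids: dict[tuple[str, int], str] = {}
    path_of_file: dict[tuple[str, int], Path] = {}

    def _study_date(pid: str, extra_days: int = 0) -> str:
        offset = (expected_offset(pid, profile.offset_modulus)
                  + extra_days) % profile.offset_modulus
        return (anchor + timedelta(days=offset)).strftime("%Y%m%d")

    for s in series_plans:
        mod_dir = root / s.provider / s.patient / f"T{s.timepoint}" / s.mod_dirname()
        series_dir = mod_dir / s.series_id
        series_dir.mkdir(parents=True, exist_ok=True)
        for k in range(s.n_slices):
            key = (s.series_id, k)
            path = series_dir / f"I{k:04d}.dcm"
            path_of_file[key] = path
            if s.duplicate_of is not None:
                src_key = (s.duplicate_of.series_id, k)
                pixels = slice_images[src_key]
                uid = slice_uids[src_key]  # copies keep the (0002,0003) value
            else:
                defect = deid_of_file.get(key)
                if defect == "burnt_in_report":
                    pixels = make_report_image(rng, params.image_size)
                else:
                    pixels = make_phantom_image(rng, params.image_size)
                uid = uids.next()
            slice_images[key] = pixels
            slice_uids[key] = uid
            defect = deid_of_file.get(key)
            # an incorrectly hashed date lands at least one day off-offset
            extra = 1 if defect == "date_hash_wrong_id" else 0
            write_dicom_instance(
                path, pixels, uid=uid,
                modality_code=s.modality,
                patient_id=s.patient,
                study_date=_study_date(s.patient, extra_days=extra),
                manufacturer=_MANUFACTURERS[uids.counter % 3],
                slice_thickness=_THICKNESS.get(s.modality, "3.0"),
                field_strength="3.0" if s.modality == "MR" else None,
                kernel="STANDARD" if s.modality in ("CT", "FUSCT") else None,
                patient_sex="F" if defect == "retained_sex_tag" else None,
                patient_age="063Y" if defect == "retained_age_tag" else None)
            if defect is not None:
                manifest.defects.append({
                    "class": defect,
                    "record": path.relative_to(root).as_posix()})
        if s.mask_shape is not None:
            _write_mask(mod_dir / f"{s.series_id}_annotation.nii.gz",
                        s.mask_shape, s.mask_label, rng)
        if s.duplicate_of is not None:
            manifest.duplicate_pairs.append({
                "class": ("duplicate_series_inter" if s.inter
                          else "duplicate_series_intra"),
                "source": (Path(s.duplicate_of.provider)
                           / s.duplicate_of.patient
                           / f"T{s.duplicate_of.timepoint}"
                           / s.duplicate_of.mod_dirname()
                           / s.duplicate_of.series_id).as_posix(),
                "copy": series_dir.relative_to(root).as_posix(),
            })

    # clinical CSVs -----------------------------------------------------------
    decl_columns = [f"modalities_t{tp}"
                    for tp in sorted(params.modalities_per_timepoint)]
    columns = ["patient_id", "provider_id", "cancer_type", "sex", "age",
               "grade", "histological_type", "stage", "biopsy", "er_status",
               "pr_status", "her2_status", "primary_diagnosis_text",
               *decl_columns]
    df = pd.DataFrame(patients)[columns]
    for cancer in sorted(df["cancer_type"].unique()):
        df[df["cancer_type"] == cancer].to_csv(
            root / f"clinical_{cancer}.csv", index=False)

    # -- manifest -------------------------------------------------------------
    n_records = len(slots)
    n_masks = len(mask_series)
    manifest.counts = {
        "providers": len(providers),
        "patients": n_patients,
        "series": len(series_plans),
        "files": n_files,
        "modality_records": n_records,
        "assessed_values": n_assessed_values,
        "crosslink_evaluations": n_patients,
        "masks": n_masks,
        "duplicate_pairs": k_dup_intra + k_dup_inter,
    }
    sex_by_provider: dict[str, dict[str, int]] = {}
    for rec in patients:
        per = sex_by_provider.setdefault(rec["provider_id"], {})
        per[rec["sex"]] = per.get(rec["sex"], 0) + 1
    manifest.counts["sex_by_provider"] = sex_by_provider
    n_bad_files = sum(deid_counts.values())
    manifest.expected = {
        "completeness": ratio_percentage(n_patients - k_miss, n_patients),
        "validity": ratio_percentage(n_assessed_values - k_invalid,
                                     n_assessed_values),
        "consistency": ratio_percentage(n_patients - k_break, n_patients),
        "integrity": ratio_percentage(n_records - k_mm - k_nv, n_records),
        "anonymization": ratio_percentage(n_files - n_bad_files, n_files),
        "annotation_consistency": ratio_percentage(
            n_masks - mask_counts["mask_roi_mismatch"]
            - mask_counts["mask_slice_mismatch"], n_masks)
        if params.with_annotations else None,
        "empty_mask_rate": ratio_percentage(
            mask_counts["empty_mask"], n_masks, decimals=1)
        if params.with_annotations else None,
    }
    manifest.save(root / "ground_truth_manifest.json")
    return root, manifest
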