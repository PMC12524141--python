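"""Repository scanning and readers for the three file families.

A repository is laid out as::

    <PROVIDER>/<PATIENT_ID>/T<n>/<MODALITY>/<SERIES_ID>/*.dcm

with annotation masks stored as sibling files of the series directory,
``<SERIES_ID>_annotation.nii`` or ``.nii.gz``, and one clinical template CSV
per cancer type at the repository root (``clinical_<cancer>.csv``).  The
layout is configurable through :class:`LayoutSpec`; the default matches the
provider / patient / timepoint / modality granularity every downstream
analysis uses.

Only headers are read during scanning (``stop_before_pixels``); pixel data is
loaded lazily by the modules that need it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

logger = logging.getLogger(__name__)

#: Modality directory codes accepted by the default layout.
MODALITY_CODES = ("CT", "MR", "MG", "US", "PT", "FUSCT", "FUSPT", "XRAY")

#: Cell contents treated as the single missing-value sentinel (case-insensitive).
MISSING_SENTINELS = frozenset({"", "na", "n/a", "null", "none", "nan"})

#: DICOM date tags inspected by the de-identification audit.
DATE_TAG_NAMES = ("StudyDate", "SeriesDate", "AcquisitionDate", "ContentDate")


class RepositoryError(Exception):
    """Fatal problem with the repository tree or one of its files."""


@dataclass
class LayoutSpec:
    """Naming convention of the repository tree."""

    timepoint_pattern: str = r"^T(\d+)$"
    modality_codes: Sequence[str] = MODALITY_CODES
    dicom_suffix: str = ".dcm"
    annotation_suffix: str = "_annotation"
    clinical_glob: str = "clinical_*.csv"

    def parse_timepoint(self, name: str) -> Optional[int]:
        m = re.match(self.timepoint_pattern, name)
        return int(m.group(1)) if m else None

    def normalize_modality(self, name: str) -> tuple[str, bool]:
        """Return (modality code, naming_ok).

        A directory that is not an exact code but contains one as a prefix
        (e.g. ``ct_scan``) is indexed under the matching code with a
        naming-violation flag, so integrity can consume it.
        """
        if name in self.modality_codes:
            return name, True
        upper = name.upper()
        if upper in self.modality_codes:
            return upper, False
        for code in sorted(self.modality_codes, key=len, reverse=True):
            if upper.startswith(code):
                return code, False
        return name, False


@dataclass
class InstanceHeader:
    """Audit-relevant tags of one DICOM instance; absent tags stay ``None``."""

    path: Path
    media_storage_sop_uid: Optional[str] = None
    sop_class_uid: Optional[str] = None
    modality: Optional[str] = None
    rows: Optional[int] = None
    columns: Optional[int] = None
    pixel_spacing: Optional[tuple[float, float]] = None
    slice_thickness: Optional[float] = None
    manufacturer: Optional[str] = None
    magnetic_field_strength: Optional[float] = None
    convolution_kernel: Optional[str] = None
    patient_id: Optional[str] = None
    patient_sex: Optional[str] = None
    patient_age: Optional[str] = None
    patient_name: Optional[str] = None
    patient_birth_date: Optional[str] = None
    burned_in_annotation: Optional[str] = None
    dates: dict[str, str] = field(default_factory=dict)


@dataclass
class SeriesRecord:
    """One imaging series directory."""

    path: Path
    provider_id: str
    patient_id: str
    timepoint: Optional[int]
    modality: str
    series_id: str
    instances: list[InstanceHeader] = field(default_factory=list)
    mask_paths: list[Path] = field(default_factory=list)
    naming_violation: bool = False
    raw_modality_dirname: str = ""
    skipped_files: list[Path] = field(default_factory=list)

    @property
    def instance_count(self) -> int:
        return len(self.instances)


@dataclass
class AnnotationVolume:
    """A NIfTI annotation mask linked to a series."""

    path: Path
    rows: int
    columns: int
    slice_count: int
    labels: frozenset[int]
    data: np.ndarray
    series_path: Optional[Path] = None
    timepoint: Optional[int] = None


@dataclass
class PatientEntry:
    patient_id: str
    #: timepoint ordinal -> modality code -> series list
    timepoints: dict[int, dict[str, list[SeriesRecord]]] = field(default_factory=dict)

    def iter_series(self) -> Iterator[SeriesRecord]:
        for tp in sorted(self.timepoints):
            for mod in sorted(self.timepoints[tp]):
                yield from self.timepoints[tp][mod]

    def modalities_at(self, timepoint: int) -> dict[str, list[SeriesRecord]]:
        return self.timepoints.get(timepoint, {})

    @property
    def has_followup_imaging(self) -> bool:
        return any(tp > 1 and mods for tp, mods in self.timepoints.items())


@dataclass
class ProviderEntry:
    provider_id: str
    patients: dict[str, PatientEntry] = field(default_factory=dict)


@dataclass
class RepositoryIndex:
    root: Path
    providers: dict[str, ProviderEntry] = field(default_factory=dict)
    clinical_paths: list[Path] = field(default_factory=list)
    skipped_files: list[Path] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def iter_series(self) -> Iterator[SeriesRecord]:
        for prov in sorted(self.providers):
            for pid in sorted(self.providers[prov].patients):
                yield from self.providers[prov].patients[pid].iter_series()

    def iter_instances(self) -> Iterator[tuple[SeriesRecord, InstanceHeader]]:
        for series in self.iter_series():
            for inst in series.instances:
                yield series, inst

    def get_patient(self, patient_id: str) -> Optional[PatientEntry]:
        for prov in self.providers.values():
            if patient_id in prov.patients:
                return prov.patients[patient_id]
        return None

    @property
    def patient_count(self) -> int:
        return sum(len(p.patients) for p in self.providers.values())

    @property
    def series_count(self) -> int:
        return sum(1 for _ in self.iter_series())

    @property
    def instance_count(self) -> int:
        return sum(s.instance_count for s in self.iter_series())


# ---------------------------------------------------------------------------
# Readers


def read_series_header(series_dir: Path, layout: LayoutSpec | None = None) -> SeriesRecord:
    """Read all part-10 headers of one series directory.

    Unparseable files are skipped with a warning and recorded in
    ``skipped_files``; a directory with zero readable instances raises
    :class:`RepositoryError`.
    """
    layout = layout or LayoutSpec()
    series_dir = Path(series_dir)
    record = SeriesRecord(
        path=series_dir,
        provider_id="",
        patient_id="",
        timepoint=None,
        modality="",
        series_id=series_dir.name,
    )
    files = sorted(p for p in series_dir.iterdir() if p.suffix == layout.dicom_suffix)
    for f in files:
        try:
            ds = pydicom.dcmread(f, stop_before_pixels=True)
        except Exception as exc:  # pragma: no cover - corrupt-file path
            logger.warning("skipping unparseable DICOM file %s: %s", f, exc)
            record.skipped_files.append(f)
            continue
        record.instances.append(_header_from_dataset(f, ds))
    if not record.instances and not record.skipped_files:
        raise RepositoryError(f"no DICOM instances in {series_dir}")
    if not record.instances:
        raise RepositoryError(f"zero readable DICOM instances in {series_dir}")
    return record


def _get(ds: pydicom.Dataset, name: str):
    return ds.get(name) if name in ds else None


def _header_from_dataset(path: Path, ds: pydicom.Dataset) -> InstanceHeader:
    meta_uid = None
    if getattr(ds, "file_meta", None) is not None:
        meta_uid = str(ds.file_meta.get("MediaStorageSOPInstanceUID", "")) or None
    spacing = None
    if "PixelSpacing" in ds and ds.PixelSpacing is not None:
        try:
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        except (TypeError, ValueError, IndexError):
            spacing = None
    dates = {}
    for tag in DATE_TAG_NAMES:
        if tag in ds and ds.get(tag):
            dates[tag] = str(ds.get(tag))

    def _float(name):
        v = _get(ds, name)
        try:
            return float(v) if v is not None else None
        except (TypeError, ValueError):
            return None

    def _str(name):
        v = _get(ds, name)
        return str(v) if v is not None else None

    def _int(name):
        v = _get(ds, name)
        return int(v) if v is not None else None

    return InstanceHeader(
        path=path,
        media_storage_sop_uid=meta_uid,
        sop_class_uid=_str("SOPClassUID"),
        modality=_str("Modality"),
        rows=_int("Rows"),
        columns=_int("Columns"),
        pixel_spacing=spacing,
        slice_thickness=_float("SliceThickness"),
        manufacturer=_str("Manufacturer"),
        magnetic_field_strength=_float("MagneticFieldStrength"),
        convolution_kernel=_str("ConvolutionKernel"),
        patient_id=_str("PatientID"),
        patient_sex=_str("PatientSex"),
        patient_age=_str("PatientAge"),
        patient_name=_str("PatientName"),
        patient_birth_date=_str("PatientBirthDate"),
        burned_in_annotation=_str("BurnedInAnnotation"),
        dates=dates,
    )


def read_annotation(path: Path) -> AnnotationVolume:
    """Load a NIfTI-1 mask; all-zero volumes are valid."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise RepositoryError(f"cannot read NIfTI annotation {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
    data = np.rint(np.asarray(data)).astype(np.int32)
    if data.min() < 0:
        raise RepositoryError(f"annotation {path} contains negative label codes")
    labels = frozenset(int(v) for v in np.unique(data))
    return AnnotationVolume(
        path=path,
        rows=int(data.shape[0]),
        columns=int(data.shape[1]),
        slice_count=int(data.shape[2]),
        labels=labels,
        data=data,
    )


# ---------------------------------------------------------------------------
# Clinical tables


@dataclass
class TemplateSchema:
    """Column contract of the clinical template."""

    patient_id_column: str = "patient_id"
    provider_column: str = "provider_id"
    cancer_type_column: str = "cancer_type"
    fields: Sequence[str] = ()

    def known_columns(self) -> set[str]:
        return {self.patient_id_column, self.provider_column,
                self.cancer_type_column, *self.fields}


@dataclass
class ClinicalTable:
    """One record per patient; missing values normalized to ``None``."""

    df: pd.DataFrame
    schema: TemplateSchema
    unknown_columns: list[str] = field(default_factory=list)
    source: Optional[Path] = None

    @property
    def patient_ids(self) -> list[str]:
        return list(self.df[self.schema.patient_id_column])

    def value(self, patient_id: str, field_name: str):
        row = self.df.loc[self.df[self.schema.patient_id_column] == patient_id]
        if row.empty or field_name not in self.df.columns:
            return None
        v = row.iloc[0][field_name]
        return None if pd.isna(v) else v

    def records(self) -> Iterator[dict]:
        for _, row in self.df.iterrows():
            yield {k: (None if pd.isna(v) else v) for k, v in row.items()}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       schema: TemplateSchema | None = None) -> "ClinicalTable":
        schema = schema or TemplateSchema(fields=tuple(
            c for c in df.columns if c not in ("patient_id", "provider_id", "cancer_type")))
        return cls(df=_normalize_missing(df.copy()), schema=schema)

    @staticmethod
    def concat(tables: Sequence["ClinicalTable"]) -> "ClinicalTable":
        if not tables:
            raise ValueError("no clinical tables to combine")
        df = pd.concat([t.df for t in tables], ignore_index=True)
        return ClinicalTable(df=df, schema=tables[0].schema,
                             unknown_columns=sorted({c for t in tables
                                                     for c in t.unknown_columns}))


def _normalize_missing(df: pd.DataFrame) -> pd.DataFrame:
    def norm(v):
        if pd.isna(v):
            return pd.NA
        if isinstance(v, str) and v.strip().lower() in MISSING_SENTINELS:
            return pd.NA
        return v

    return df.map(norm)


def load_clinical_table(path: Path, schema: TemplateSchema) -> ClinicalTable:
    """Load one template CSV.

    Empty strings and the "NA"-family sentinels normalize to the single
    missing marker; unknown columns are retained but flagged; duplicated
    patient ids are a fatal error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema.patient_id_column not in df.columns:
        raise RepositoryError(
            f"{path}: missing required column '{schema.patient_id_column}'")
    df = _normalize_missing(df)
    pids = df[schema.patient_id_column]
    if pids.isna().any():
        raise RepositoryError(f"{path}: empty patient_id cells")
    dupes = pids[pids.duplicated()].tolist()
    if dupes:
        raise RepositoryError(f"{path}: duplicated patient ids: {sorted(set(dupes))}")
    unknown = sorted(set(df.columns) - schema.known_columns())
    return ClinicalTable(df=df, schema=schema, unknown_columns=unknown, source=path)


# ---------------------------------------------------------------------------
# Scanner


def scan_repository(root_path: Path, layout: LayoutSpec | None = None) -> RepositoryIndex:
    """Scan a repository root into a :class:`RepositoryIndex`.

    Deterministic: directories are visited in lexicographic order, so two
    scans of the same tree produce identical indices.  Directories violating
    the naming convention are indexed with a naming-violation flag; they are
    never silently dropped.
    """
    layout = layout or LayoutSpec()
    root = Path(root_path)
    if not root.is_dir():
        raise RepositoryError(f"repository root {root} does not exist")
    index = RepositoryIndex(root=root)
    index.clinical_paths = sorted(root.glob(layout.clinical_glob))

    for prov_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        provider = ProviderEntry(provider_id=prov_dir.name)
        for pat_dir in sorted(p for p in prov_dir.iterdir() if p.is_dir()):
            patient = PatientEntry(patient_id=pat_dir.name)
            for tp_dir in sorted(p for p in pat_dir.iterdir() if p.is_dir()):
                tp = layout.parse_timepoint(tp_dir.name)
                if tp is None:
                    index.warnings.append(
                        f"unrecognized timepoint directory: {tp_dir}")
                    continue
                for mod_dir in sorted(p for p in tp_dir.iterdir() if p.is_dir()):
                    code, ok = layout.normalize_modality(mod_dir.name)
                    for series_dir in sorted(p for p in mod_dir.iterdir()
                                             if p.is_dir()):
                        try:
                            series = read_series_header(series_dir, layout)
                        except RepositoryError as exc:
                            index.warnings.append(str(exc))
                            continue
                        series.provider_id = provider.provider_id
                        series.patient_id = patient.patient_id
                        series.timepoint = tp
                        series.modality = code
                        series.naming_violation = not ok
                        series.raw_modality_dirname = mod_dir.name
                        series.mask_paths = sorted(
                            p for p in mod_dir.iterdir()
                            if p.is_file()
                            and p.name.startswith(series_dir.name + layout.annotation_suffix)
                            and (p.name.endswith(".nii") or p.name.endswith(".nii.gz")))
                        index.skipped_files.extend(series.skipped_files)
                        patient.timepoints.setdefault(tp, {}).setdefault(
                            code, []).append(series)
            provider.patients[patient.patient_id] = patient
        index.providers[provider.provider_id] = provider
    return index


def load_annotations(index: RepositoryIndex) -> list[AnnotationVolume]:
    """Load every mask linked in the index, carrying series path and timepoint."""
    volumes = []
    for series in index.iter_series():
        for mp in series.mask_paths:
            vol = read_annotation(mp)
            vol.series_path = series.path
            vol.timepoint = series.timepoint
            volumes.append(vol)
    return volumes
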