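"""Acquisition-attribute extraction and bias/diversity profiling.

Numeric attributes (slice thickness, pixel spacing, magnetic field strength)
are summarized as ``median [q1 q3]`` with quartiles by linear interpolation
between order statistics (the common type-7 convention, switchable to
nearest-rank); categorical attributes (manufacturer, convolution kernel,
in-plane matrix) as percentage shares to one decimal, with rare categories
collapsible into "Other".  Profiles are per-instance by default; the image-
and patient-level counts behind each categorical share are both carried so
vendor diversity can be read either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clinical_metrics import ratio_percentage, round_half_up
from .repo_model import RepositoryIndex

#: attribute name -> (header field, numeric?) applied to every modality
_COMMON_ATTRS = {
    "slice_thickness_mm": ("slice_thickness", True),
    "pixel_spacing_mm": ("pixel_spacing", True),
    "roi_rows": ("rows", False),
    "roi_columns": ("columns", False),
    "manufacturer": ("manufacturer", False),
}
#: modality-specific extras
_MODALITY_ATTRS = {
    "CT": {"convolution_kernel": ("convolution_kernel", False)},
    "FUSCT": {"convolution_kernel": ("convolution_kernel", False)},
    "MR": {"magnetic_field_strength_t": ("magnetic_field_strength", True)},
}


def default_attribute_spec() -> dict[str, dict[str, tuple[str, bool]]]:
    """Per-modality attribute extraction spec (extensible via config)."""
    spec = {}
    for modality in ("CT", "MR", "MG", "US", "PT", "FUSCT", "FUSPT", "XRAY"):
        attrs = dict(_COMMON_ATTRS)
        attrs.update(_MODALITY_ATTRS.get(modality, {}))
        spec[modality] = attrs
    return spec


def extract_attributes(index: RepositoryIndex,
                       spec: dict[str, dict[str, tuple[str, bool]]] | None = None,
                       cancer_of_patient: dict[str, str] | None = None,
                       ) -> pd.DataFrame:
    """One row per (instance, attribute): cancer, modality, provider, patient,
    attribute, value, numeric flag.  Absent tags are recorded with value None.
    """
    spec = spec or default_attribute_spec()
    cancer_of_patient = cancer_of_patient or {}
    rows = []
    for series, inst in index.iter_instances():
        attrs = spec.get(series.modality)
        if attrs is None:
            continue
        cancer = cancer_of_patient.get(series.patient_id, "unknown")
        for attr_name, (field_name, numeric) in attrs.items():
            value = getattr(inst, field_name, None)
            if field_name == "pixel_spacing" and value is not None:
                value = value[0]  # row spacing in mm
            rows.append({
                "cancer": cancer, "modality": series.modality,
                "provider": series.provider_id, "patient": series.patient_id,
                "attribute": attr_name,
                "value": value, "numeric": numeric,
            })
    return pd.DataFrame(
        rows, columns=["cancer", "modality", "provider", "patient",
                       "attribute", "value", "numeric"])


@dataclass
class NumericProfile:
    median: float
    q1: float
    q3: float
    n: int

    def format(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"
        return f"{fmt(self.median)} [{fmt(self.q1)} {fmt(self.q3)}]"


def numeric_profile(values: Sequence[float],
                    method: str = "linear") -> NumericProfile:
    """Median with first and third quartile.

    ``method='linear'`` interpolates between order statistics; ``'nearest'``
    uses the nearest-rank convention.
    """
    vals = np.asarray([float(v) for v in values], dtype=np.float64)
    if vals.size == 0:
        raise ValueError("numeric_profile undefined for an empty sample")
    if method not in ("linear", "nearest"):
        raise ValueError(f"unknown quartile method {method!r}")
    q1, med, q3 = np.percentile(vals, [25, 50, 75], method=method)
    return NumericProfile(median=float(med), q1=float(q1), q3=float(q3),
                          n=int(vals.size))


def categorical_profile(values: Sequence[str], floor: float = 0.0,
                        ) -> dict[str, float]:
    """Category -> percentage share (1 decimal) over non-missing values.

    Categories with share below ``floor`` (a fraction) collapse into "Other".
    """
    vals = [str(v) for v in values if v is not None]
    if not vals:
        raise ValueError("categorical_profile undefined for an empty sample")
    counts: dict[str, int] = {}
    for v in vals:
        counts[v] = counts.get(v, 0) + 1
    n = len(vals)
    if floor > 0:
        collapsed: dict[str, int] = {}
        for cat, c in counts.items():
            key = cat if c / n >= floor else "Other"
            collapsed[key] = collapsed.get(key, 0) + c
        counts = collapsed
    return {cat: ratio_percentage(c, n, decimals=1)
            for cat, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))}


def profile_table(attributes: pd.DataFrame, floor: float = 0.0,
                  method: str = "linear") -> list[dict]:
    """Shape one summary row per (cancer, modality, attribute).

    Numeric attributes render as ``median [q1 q3]``; categorical ones as a
    share mapping.  Image-level n and patient-level n are both reported.
    """
    out = []
    if attributes.empty:
        return out
    for (cancer, modality, attr), grp in attributes.groupby(
            ["cancer", "modality", "attribute"], sort=True):
        present = grp[grp["value"].notna()]
        row = {"cancer": cancer, "modality": modality, "attribute": attr,
               "n_images": int(len(present)),
               "n_patients": int(present["patient"].nunique())}
        if present.empty:
            row["summary"] = None
        elif bool(grp["numeric"].iloc[0]):
            prof = numeric_profile(present["value"].tolist(), method=method)
            row["summary"] = prof.format()
            row["median"] = round_half_up(prof.median, 4)
            row["q1"] = round_half_up(prof.q1, 4)
            row["q3"] = round_half_up(prof.q3, 4)
        else:
            row["shares"] = categorical_profile(present["value"].tolist(),
                                                floor=floor)
            row["summary"] = " ".join(f"{k}: {v}%"
                                      for k, v in row["shares"].items())
        out.append(row)
    return out
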