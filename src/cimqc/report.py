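"""Pipeline orchestration and the structured quality report.

``run_pipeline`` executes the selected stages in dependency order (scan →
clinical metrics → fairness → imaging stages) over one repository root and
one rule-set, collecting every module's output into a single report dict.  A
failure inside one stage is recorded in the run log and does not abort the
others.  The report is deterministic for fixed input and configuration: no
timestamps are embedded, and every number traces to a module output.

The report validates against :data:`REPORT_SCHEMA`, a minimal JSON-schema
(type/required/properties subset) shipped with the package and enforced by
:func:`validate_report`.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .annotation_qc import evaluate_annotations
from .clinical_metrics import (completeness, consistency, integrity, validity)
from .deid_audit import anonymization_metric
from .dicom_profile import extract_attributes, profile_table
from .fairness import fairness_report
from .imaging_dedup import inter_patient_scan, intra_patient_scan, uid_screen
from .repo_model import (ClinicalTable, LayoutSpec, RepositoryIndex,
                         TemplateSchema, load_clinical_table, scan_repository)
from .rules_config import QualityRuleSet, default_ruleset

logger = logging.getLogger(__name__)

ALL_STAGES = ("clinical", "fairness", "dedup", "annot", "profile", "deid")

REPORT_SCHEMA: dict = {
    "type": "object",
    "required": ["meta", "stages_run", "clinical", "anonymization",
                 "annotation", "fairness", "dedup", "dicom_profile", "run_log"],
    "properties": {
        "meta": {
            "type": "object",
            "required": ["toolkit_version", "ruleset_digest", "repository_root"],
            "properties": {
                "toolkit_version": {"type": "string"},
                "ruleset_digest": {"type": "string"},
                "repository_root": {"type": "string"},
            },
        },
        "stages_run": {"type": "array", "items": {"type": "string"}},
        "clinical": {"type": ["object", "null"]},
        "anonymization": {"type": ["object", "null"]},
        "annotation": {"type": ["object", "null"]},
        "fairness": {"type": ["object", "null"]},
        "dedup": {"type": ["object", "null"]},
        "dicom_profile": {"type": ["array", "null"]},
        "run_log": {
            "type": "object",
            "required": ["warnings", "skipped_files", "errors"],
            "properties": {
                "warnings": {"type": "array"},
                "skipped_files": {"type": "array"},
                "errors": {"type": "array"},
            },
        },
    },
}

_JSON_TYPES = {
    "object": dict, "array": list, "string": str, "number": (int, float),
    "integer": int, "boolean": bool, "null": type(None),
}


def validate_report(report: dict, schema: dict | None = None,
                    path: str = "$") -> list[str]:
    """Structural validation against the published schema subset.

    Returns the list of violations (empty iff valid).
    """
    schema = schema if schema is not None else REPORT_SCHEMA
    errors: list[str] = []
    expected = schema.get("type")
    if expected is not None:
        types = expected if isinstance(expected, list) else [expected]
        if not any(isinstance(report, _JSON_TYPES[t]) and not
                   (t != "boolean" and isinstance(report, bool) and t in
                    ("integer", "number"))
                   for t in types):
            errors.append(f"{path}: expected type {expected}, "
                          f"got {type(report).__name__}")
            return errors
    if isinstance(report, dict):
        for key in schema.get("required", []):
            if key not in report:
                errors.append(f"{path}: missing required key '{key}'")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                errors.extend(validate_report(report[key], sub, f"{path}.{key}"))
    if isinstance(report, list) and "items" in schema:
        for i, item in enumerate(report):
            errors.extend(validate_report(item, schema["items"], f"{path}[{i}]"))
    return errors


def export_schema(path: Path) -> None:
    Path(path).write_text(json.dumps(REPORT_SCHEMA, indent=2, sort_keys=True))


def ruleset_digest(ruleset: QualityRuleSet) -> str:
    blob = json.dumps(ruleset.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_clinical_tables(index: RepositoryIndex,
                         schema: TemplateSchema | None = None,
                         ) -> Optional[ClinicalTable]:
    schema = schema or TemplateSchema(fields=(
        "sex", "age", "grade", "histological_type", "stage", "biopsy",
        "er_status", "pr_status", "her2_status", "primary_diagnosis_text",
        "modalities_t1", "modalities_t2", "modalities_t3"))
    tables = [load_clinical_table(p, schema) for p in index.clinical_paths]
    return ClinicalTable.concat(tables) if tables else None


def run_pipeline(root: Path, ruleset: QualityRuleSet | None = None,
                 stages: Sequence[str] | None = None, grade: str = "high",
                 layout: LayoutSpec | None = None) -> dict:
    """Run the selected stages over a repository and assemble the report."""
    ruleset = ruleset or default_ruleset()
    stages = tuple(stages) if stages else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; "
                         f"choose from {ALL_STAGES}")
    if not stages:
        raise ValueError("no stages selected")
    errors: list[str] = []
    report: dict = {
        "meta": {
            "toolkit_version": __version__,
            "ruleset_digest": ruleset_digest(ruleset),
            "repository_root": str(root),
        },
        "stages_run": sorted(stages),
        "clinical": None, "anonymization": None, "annotation": None,
        "fairness": None, "dedup": None, "dicom_profile": None,
    }
    index = scan_repository(root, layout)
    table = None
    try:
        table = load_clinical_tables(index)
    except Exception as exc:
        errors.append(f"clinical tables: {exc}")
    cancer_of_patient = {}
    if table is not None:
        for rec in table.records():
            cancer_of_patient[str(rec["patient_id"])] = str(
                rec.get("cancer_type"))

    def _stage(name, fn):
        if name not in stages:
            return
        try:
            fn()
        except Exception as exc:  # stage isolation
            logger.exception("stage %s failed", name)
            errors.append(f"{name}: {exc}")

    def _clinical():
        if table is None:
            raise RuntimeError("no clinical tables found")
        report["clinical"] = {
            "completeness": completeness(table, index, ruleset).to_dict(),
            "validity": validity(table, ruleset).to_dict(),
            "consistency": consistency(table, ruleset).to_dict(),
            "integrity": integrity(table, index, ruleset).to_dict(),
        }

    def _fairness():
        if table is None:
            raise RuntimeError("no clinical tables found")
        report["fairness"] = fairness_report(table, ruleset).to_dict()

    def _dedup():
        groups = uid_screen(index)
        intra, inter = [], []
        for prov in sorted(index.providers):
            provider = index.providers[prov]
            for pid in sorted(provider.patients):
                f = intra_patient_scan(provider.patients[pid], grade, ruleset)
                if f.pairs:
                    intra.append(f)
            f = inter_patient_scan(provider, grade, ruleset)
            if f.pairs:
                inter.append(f)

        def _merge(findings, scope):
            merged = {"scope": scope, "grade": grade,
                      "comparisons": sum(f.comparisons_performed
                                         for f in findings),
                      "flagged": sum(len(f.flagged_pairs) for f in findings),
                      "pairs": [p.to_dict() for f in findings
                                for p in f.flagged_pairs]}
            return merged

        report["dedup"] = {
            "uid_groups": [g.to_dict() for g in groups],
            "intra": _merge(intra, "intra"),
            "inter": _merge(inter, "inter"),
        }

    def _annot():
        report["annotation"] = evaluate_annotations(
            index, ruleset, cancer_of_patient).to_dict()

    def _profile():
        attrs = extract_attributes(index, cancer_of_patient=cancer_of_patient)
        report["dicom_profile"] = profile_table(
            attrs, floor=ruleset.categorical_other_floor)

    def _deid():
        report["anonymization"] = anonymization_metric(index, ruleset).to_dict()

    _stage("clinical", _clinical)
    _stage("fairness", _fairness)
    _stage("dedup", _dedup)
    _stage("annot", _annot)
    _stage("profile", _profile)
    _stage("deid", _deid)

    report["run_log"] = {
        "warnings": list(index.warnings),
        "skipped_files": [str(p) for p in index.skipped_files],
        "errors": errors,
    }
    violations = validate_report(report)
    if violations:  # defensive; the assembly above always satisfies the schema
        raise RuntimeError(f"report schema violations: {violations}")
    return report


# ---------------------------------------------------------------------------
# Writers


def _text_summary(report: dict) -> str:
    lines = [f"cimqc quality report (toolkit {report['meta']['toolkit_version']})",
             f"repository: {report['meta']['repository_root']}", ""]
    clinical = report.get("clinical") or {}
    for dim in ("completeness", "validity", "consistency", "integrity"):
        m = clinical.get(dim)
        if m:
            pct = "undefined" if m["percentage"] is None else f"{m['percentage']}%"
            lines.append(f"{dim:>14}: {pct}  ({m['numerator']}/{m['denominator']})")
    anon = report.get("anonymization")
    if anon:
        m = anon["metric"]
        pct = "undefined" if m["percentage"] is None else f"{m['percentage']}%"
        lines.append(f"{'anonymization':>14}: {pct}  "
                     f"({m['numerator']}/{m['denominator']} compliant)")
    ann = report.get("annotation")
    if ann:
        m = ann["consistency"]
        pct = "undefined" if m["percentage"] is None else f"{m['percentage']}%"
        lines.append(f"{'annotation':>14}: {pct}  "
                     f"({m['numerator']}/{m['denominator']} consistent, "
                     f"empty rate {ann['empty_rate']}%)")
    dedup = report.get("dedup")
    if dedup:
        lines.append(f"{'dedup':>14}: intra {dedup['intra']['flagged']}/"
                     f"{dedup['intra']['comparisons']} flagged, "
                     f"inter {dedup['inter']['flagged']}/"
                     f"{dedup['inter']['comparisons']} flagged, "
                     f"{len(dedup['uid_groups'])} UID groups")
    if report.get("run_log", {}).get("errors"):
        lines.append("")
        lines.append("stage errors: " + "; ".join(report["run_log"]["errors"]))
    return "\n".join(lines) + "\n"


def _csv_bundle(report: dict, out_dir: Path) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(name: str, header: list[str], rows: list[list]):
        path = out_dir / name
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)
        written.append(path)

    fairness = report.get("fairness")
    if fairness:
        rows = [[d["site"], d["variable"], cls, v["count"], v["percentage"]]
                for d in fairness["distributions"]
                for cls, v in d["classes"].items()]
        _write("fairness_distributions.csv",
               ["site", "variable", "class", "count", "percentage"], rows)
    dedup = report.get("dedup")
    if dedup:
        rows = [[scope, report["dedup"][scope]["grade"], p["series_a"],
                 p["series_b"], p["similarity_percentage"], p["timepoint_gap"]]
                for scope in ("intra", "inter")
                for p in dedup[scope]["pairs"]]
        _write("dedup_findings.csv",
               ["scope", "grade", "series_a", "series_b",
                "similarity_percentage", "timepoint_gap"], rows)
    anon = report.get("anonymization")
    if anon:
        _write("deid_violations.csv", ["path", "category", "detail", "severity"],
               [[v["path"], v["category"], v["detail"], v["severity"]]
                for v in anon["violations"]])
    profile = report.get("dicom_profile")
    if profile:
        _write("dicom_profile.csv",
               ["cancer", "modality", "attribute", "n_images", "n_patients",
                "summary"],
               [[r["cancer"], r["modality"], r["attribute"], r["n_images"],
                 r["n_patients"], r.get("summary")] for r in profile])
    clinical = report.get("clinical")
    if clinical:
        rows = []
        for dim, m in clinical.items():
            for f in m["failing_records"]:
                rows.append([dim, f["record"], "; ".join(f["reasons"])])
        _write("clinical_failing_records.csv", ["dimension", "record", "reasons"],
               rows)
    return written


def write_report(report: dict, out: Path, format: str = "json") -> list[Path]:
    """Serialize the report; JSON output is schema-validated first."""
    out = Path(out)
    if format == "json":
        violations = validate_report(report)
        if violations:
            raise ValueError(f"report does not validate: {violations}")
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(json.dumps(report, indent=2, sort_keys=True))
        return [out]
    if format == "text":
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(_text_summary(report))
        return [out]
    if format == "csv-bundle":
        return _csv_bundle(report, out)
    raise ValueError(f"unknown report format {format!r}")
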