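"""Per-site subgroup representation profiling.

Fairness here is the balanced representation of sex, age bin, cancer type and
cancer grade per recruiting site, reported as normalized class percentages
(2 decimals, half-up) over the patients with the variable reported, plus
qualitative flags: a missing variable at a site, an absent class of a closed
class set, and dominance of a single class above a configurable share.

No scalar fairness index is computed: the distributions and flags themselves
are the deliverable, feeding human curation rather than a pass/fail gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .clinical_metrics import ratio_percentage
from .repo_model import ClinicalTable
from .rules_config import QualityRuleSet

logger = logging.getLogger(__name__)

FAIRNESS_VARIABLES = ("sex", "age_bin", "cancer_type", "cancer_grade")

#: template column backing each fairness variable
_VARIABLE_COLUMNS = {
    "sex": "sex",
    "age_bin": "age",
    "cancer_type": "histological_type",
    "cancer_grade": "grade",
}


def assign_age_bin(age: float, edges: Sequence[int]) -> str:
    """Left-open right-closed bins ``(e_i, e_{i+1}]`` with overflow bins.

    Ages at or below the first edge fall into the low overflow bin, ages
    above the last edge into the high overflow bin.  Negative ages are a
    validity concern and must be filtered before binning.
    """
    if age < 0:
        raise ValueError(f"negative age {age}")
    lo, hi = edges[0], edges[-1]
    if age <= lo:
        return f"≤{lo}"
    if age > hi:
        return f">{hi}"
    for left, right in zip(edges[:-1], edges[1:]):
        if left < age <= right:
            return f"({left}, {right}]"
    raise AssertionError("unreachable")  # edges are increasing and cover (lo, hi]


def age_bin_labels(edges: Sequence[int]) -> list[str]:
    labels = [f"≤{edges[0]}"]
    labels += [f"({l}, {r}]" for l, r in zip(edges[:-1], edges[1:])]
    labels.append(f">{edges[-1]}")
    return labels


@dataclass
class NormalizedDistribution:
    variable: str
    site: str
    counts: dict[str, int]
    total: int
    missing: int = 0

    @property
    def percentages(self) -> dict[str, Optional[float]]:
        return {cls: ratio_percentage(n, self.total)
                for cls, n in self.counts.items()}

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "site": self.site,
            "n": self.total,
            "missing": self.missing,
            "classes": {
                cls: {"count": n, "percentage": ratio_percentage(n, self.total)}
                for cls, n in self.counts.items()},
        }


@dataclass
class FairnessFlag:
    site: str
    variable: str
    kind: str  # absent_subgroup | dominance | missing_variable
    detail: str


@dataclass
class FairnessReport:
    distributions: list[NormalizedDistribution] = field(default_factory=list)
    flags: list[FairnessFlag] = field(default_factory=list)

    def get(self, site: str, variable: str) -> Optional[NormalizedDistribution]:
        for d in self.distributions:
            if d.site == site and d.variable == variable:
                return d
        return None

    def to_dict(self) -> dict:
        return {
            "distributions": [d.to_dict() for d in self.distributions],
            "flags": [vars(f).copy() for f in self.flags],
        }


def _closed_classes(variable: str, ruleset: QualityRuleSet) -> Optional[list[str]]:
    """Closed class sets are listed even at zero count (age bins, grades)."""
    if variable == "age_bin":
        return age_bin_labels(ruleset.age_bin_edges)
    if variable == "cancer_grade":
        rule = ruleset.field_rules.get(_VARIABLE_COLUMNS[variable])
        return list(rule.allowed) if rule and rule.allowed else None
    if variable == "sex":
        rule = ruleset.field_rules.get("sex")
        return list(rule.allowed) if rule and rule.allowed else ["M", "F"]
    return None


def subgroup_distribution(table: ClinicalTable, variable: str, site: str,
                          ruleset: QualityRuleSet | None = None,
                          ) -> NormalizedDistribution:
    """Normalized class distribution of one variable at one site.

    The denominator is the number of patients at the site with the variable
    reported; the missing count is carried alongside.  Order of patients never
    affects the result.
    """
    from .rules_config import default_ruleset
    ruleset = ruleset or default_ruleset()
    if variable not in FAIRNESS_VARIABLES:
        raise ValueError(f"unknown fairness variable {variable!r}; "
                         f"expected one of {FAIRNESS_VARIABLES}")
    column = _VARIABLE_COLUMNS[variable]
    closed = _closed_classes(variable, ruleset)
    counts: dict[str, int] = {cls: 0 for cls in closed} if closed else {}
    total = missing = 0
    for rec in table.records():
        if str(rec.get(table.schema.provider_column)) != str(site):
            continue
        value = rec.get(column) if column in table.df.columns else None
        if value is None:
            missing += 1
            continue
        if variable == "age_bin":
            try:
                age = float(value)
            except (TypeError, ValueError):
                missing += 1
                continue
            if age < 0:
                logger.warning("site %s: negative age %s excluded from fairness",
                               site, value)
                missing += 1
                continue
            cls = assign_age_bin(age, ruleset.age_bin_edges)
        else:
            cls = str(value)
        counts[cls] = counts.get(cls, 0) + 1
        total += 1
    return NormalizedDistribution(variable=variable, site=str(site),
                                  counts=counts, total=total, missing=missing)


def fairness_report(table: ClinicalTable,
                    ruleset: QualityRuleSet) -> FairnessReport:
    """All per-site distributions plus imbalance flags."""
    report = FairnessReport()
    sites = sorted({str(rec.get(table.schema.provider_column))
                    for rec in table.records()})
    cancer_by_site: dict[str, set[str]] = {s: set() for s in sites}
    for rec in table.records():
        site = str(rec.get(table.schema.provider_column))
        cancer = rec.get(table.schema.cancer_type_column)
        if cancer is not None:
            cancer_by_site[site].add(str(cancer))
    for site in sites:
        fixed_vars = {v for c in cancer_by_site[site]
                      for v in ruleset.structurally_fixed.get(c, [])}
        for variable in FAIRNESS_VARIABLES:
            dist = subgroup_distribution(table, variable, site, ruleset)
            report.distributions.append(dist)
            if dist.total == 0:
                report.flags.append(FairnessFlag(
                    site=site, variable=variable, kind="missing_variable",
                    detail=f"no non-missing '{variable}' values at site {site}"))
                continue
            closed = _closed_classes(variable, ruleset)
            if closed:
                for cls in closed:
                    if dist.counts.get(cls, 0) == 0:
                        report.flags.append(FairnessFlag(
                            site=site, variable=variable, kind="absent_subgroup",
                            detail=f"class '{cls}' absent at site {site}"))
            if variable in fixed_vars:
                continue  # single-class by construction (e.g. prostate sex)
            for cls, n in dist.counts.items():
                if n / dist.total > ruleset.dominance_share:
                    report.flags.append(FairnessFlag(
                        site=site, variable=variable, kind="dominance",
                        detail=(f"class '{cls}' holds {n}/{dist.total} "
                                f"(> {ruleset.dominance_share:.0%}) at site {site}")))
    return report
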