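"""End-to-end analysis pipeline and report rendering.

``run_pipeline`` executes read/generate -> exclusion filter -> reference-
standard classification -> confusion matrix -> metric suite -> category
summaries and tests, returning one :class:`AnalysisReport` whose every
rendered number is traceable to a field.  Rendering applies the report
conventions (half-up integer percent, CIs to one decimal, ``N.A.`` for
undefined cells) only at output time; internal values stay full precision.
"""

from __future__ import annotations

import io
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .categories import (
    CategorySummary,
    DEFAULT_CODING,
    DEFAULT_MIN_N,
    TestResult,
    chi_square_association,
    kruskal_wallis_consistency,
    pairwise_posthoc,
    summarize_by_category,
)
from .metrics import (
    CiMethod,
    ConfusionCounts,
    MetricEstimate,
    MetricName,
    build_confusion,
    compute_metrics,
    format_percent,
    metrics_by_name,
)
from .records import (
    DispatchPriority,
    DispatchRecord,
    Urgency,
    apply_exclusions,
    dichotomise_emd,
    read_register,
)
from .reference_standard import ClassifiedRecord, classify_register
from .synthetic import GeneratorConfig, generate_register


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisReport:
    overall: list[MetricEstimate]
    crosstab: pd.DataFrame  # letters x (urgent, non_urgent) counts
    confusion: ConfusionCounts
    categories: list[CategorySummary]
    tests: list[TestResult]
    exclusion_tally: dict[str, int]
    rule_tally: dict[str, int]
    n_analysed: int
    provenance: dict = field(default_factory=dict)


def _priority_crosstab(classified: Sequence[ClassifiedRecord]) -> pd.DataFrame:
    counts = Counter(
        (cr.record.emd_priority.value, cr.ems_label.value) for cr in classified
    )
    letters = [p.value for p in DispatchPriority]
    data = {
        "urgent": [counts[(ltr, "urgent")] for ltr in letters],
        "non_urgent": [counts[(ltr, "non_urgent")] for ltr in letters],
    }
    return pd.DataFrame(data, index=letters)


def run_pipeline(
    source: str | Path | Sequence[DispatchRecord] | GeneratorConfig,
    *,
    min_n: int = DEFAULT_MIN_N,
    ci_method: CiMethod = "wald",
    coding: Mapping[str, int] = DEFAULT_CODING,
    cd_ab_transport_urgent: bool = True,
    run_posthoc: bool = True,
    provenance: Mapping | None = None,
) -> AnalysisReport:
    """Run the full concordance analysis on a register.

    ``source`` may be a CSV path, an in-memory record list, or a generator
    configuration (in which case the register is simulated first).
    """
    prov = dict(provenance or {})
    prov["tool_version"] = __version__

    if isinstance(source, GeneratorConfig):
        records = generate_register(source)
        prov.update(input="<synthetic>", seed=source.seed, n_dispatches=source.n_dispatches)
    elif isinstance(source, (str, Path)):
        try:
            records, parse_report = read_register(source)
        except (OSError, ValueError) as exc:
            raise PipelineError("read", str(exc)) from exc
        prov.update(input=str(source), parse_issues=len(parse_report.issues))
    else:
        records = list(source)
        prov.setdefault("input", "<in-memory>")

    result = apply_exclusions(records)
    if not result.included:
        raise PipelineError("exclusions", "no analysable dispatches")

    classified = classify_register(result.included, cd_ab_transport_urgent=cd_ab_transport_urgent)
    confusion = build_confusion([(cr.emd_label, cr.ems_label) for cr in classified])
    overall = compute_metrics(confusion, ci_method=ci_method)
    crosstab = _priority_crosstab(classified)
    categories = summarize_by_category(classified, min_n=min_n, ci_method=ci_method)

    tests: list[TestResult] = []
    table = crosstab.to_numpy()
    if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
        tests.append(chi_square_association(table))
    n_eligible = sum(s.eligible_for_tests for s in categories)
    if n_eligible >= 2:
        tests.append(kruskal_wallis_consistency(classified, coding=coding, min_n=min_n))
        if run_posthoc:
            tests.extend(pairwise_posthoc(classified, coding=coding, min_n=min_n))

    return AnalysisReport(
        overall=overall,
        crosstab=crosstab,
        confusion=confusion,
        categories=categories,
        tests=tests,
        exclusion_tally=dict(result.reasons),
        rule_tally=dict(Counter(cr.trace.rule_fired.value for cr in classified)),
        n_analysed=len(classified),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Rendering

#: report column order for the category table
_CATEGORY_METRIC_ORDER = (
    MetricName.OVER_TRIAGE,
    MetricName.UNDER_TRIAGE,
    MetricName.EFFICIENCY,
    MetricName.SENSITIVITY,
    MetricName.SPECIFICITY,
    MetricName.PPV,
    MetricName.NPV,
)

_METRIC_HEADERS = {
    MetricName.OVER_TRIAGE: "Over-triage %",
    MetricName.UNDER_TRIAGE: "Under-triage %",
    MetricName.EFFICIENCY: "Efficiency %",
    MetricName.SENSITIVITY: "Sensitivity %",
    MetricName.SPECIFICITY: "Specificity %",
    MetricName.PPV: "PPV %",
    MetricName.NPV: "NPV %",
}


def _metric_row(estimates: Sequence[MetricEstimate]) -> dict[str, str]:
    by_name = metrics_by_name(estimates)
    return {
        _METRIC_HEADERS[name]: format_percent(by_name[name].point_percent)
        for name in _CATEGORY_METRIC_ORDER
    }


def category_table(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for s in report.categories:
        row = {"Dispatch category": s.category, "n": s.n, **_metric_row(s.metrics)}
        rows.append(row)
    return pd.DataFrame(rows)


def crosstab_table(report: AnalysisReport) -> pd.DataFrame:
    """The 4x2 priority-letter crosstab with row totals and the over-/
    under-triage summary rows, rendered as printed counts."""
    ct = report.crosstab
    by_name = metrics_by_name(report.overall)
    rows = []
    for letter in ct.index:
        urgent, non_urgent = int(ct.loc[letter, "urgent"]), int(ct.loc[letter, "non_urgent"])
        rows.append(
            {
                "EMD priority": letter,
                "EMS urgent (n)": urgent,
                "EMS non-urgent (n)": non_urgent,
                "Total (n)": urgent + non_urgent,
            }
        )
    rows.append(
        {
            "EMD priority": "Total",
            "EMS urgent (n)": int(ct["urgent"].sum()),
            "EMS non-urgent (n)": int(ct["non_urgent"].sum()),
            "Total (n)": int(ct.to_numpy().sum()),
        }
    )
    df = pd.DataFrame(rows)
    over, under = by_name[MetricName.OVER_TRIAGE], by_name[MetricName.UNDER_TRIAGE]
    df.attrs["over_triage"] = _format_estimate(over)
    df.attrs["under_triage"] = _format_estimate(under)
    return df


def _format_estimate(e: MetricEstimate) -> str:
    if not e.defined:
        return "N.A."
    return (
        f"{format_percent(e.point_percent)}% "
        f"(95% CI {format_percent(e.ci_low_percent, 1)}-{format_percent(e.ci_high_percent, 1)})"
    )


def overall_table(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for e in report.overall:
        rows.append(
            {
                "Metric": e.name.value,
                "Point %": format_percent(e.point_percent),
                "95% CI low": format_percent(e.ci_low_percent, 1) if e.defined else "N.A.",
                "95% CI high": format_percent(e.ci_high_percent, 1) if e.defined else "N.A.",
                "Numerator": e.numerator,
                "Denominator": e.denominator,
            }
        )
    return pd.DataFrame(rows)


def report_to_dict(report: AnalysisReport) -> dict:
    """JSON-serialisable view of the complete report."""

    def est(e: MetricEstimate) -> dict:
        return {
            "name": e.name.value,
            "numerator": e.numerator,
            "denominator": e.denominator,
            "point_percent": e.point_percent,
            "ci_low_percent": e.ci_low_percent,
            "ci_high_percent": e.ci_high_percent,
            "z": e.z,
        }

    def test(t: TestResult) -> dict:
        return {
            "test_name": t.test_name.value,
            "statistic": t.statistic,
            "p_value": t.p_value,
            "df": t.df,
            "adjusted_p": t.adjusted_p,
            "groups": list(t.groups) if t.groups else None,
        }

    return {
        "n_analysed": report.n_analysed,
        "confusion": vars(report.confusion).copy(),
        "crosstab": {
            letter: {
                "urgent": int(report.crosstab.loc[letter, "urgent"]),
                "non_urgent": int(report.crosstab.loc[letter, "non_urgent"]),
            }
            for letter in report.crosstab.index
        },
        "overall": [est(e) for e in report.overall],
        "categories": [
            {
                "category": s.category,
                "n": s.n,
                "confusion": vars(s.confusion).copy(),
                "emd_urgent_n": s.emd_urgent_n,
                "emd_non_urgent_n": s.emd_non_urgent_n,
                "eligible_for_tests": s.eligible_for_tests,
                "metrics": [est(e) for e in s.metrics],
            }
            for s in report.categories
        ],
        "tests": [test(t) for t in report.tests],
        "exclusion_tally": report.exclusion_tally,
        "rule_tally": report.rule_tally,
        "provenance": report.provenance,
    }


RenderFormat = Literal["text", "csv", "json"]


def render_tables(report: AnalysisReport, format: RenderFormat = "text") -> str:
    """Render the three headline tables (overall metrics, priority crosstab,
    category table) in the requested format. Deterministic for equal reports."""
    if format == "json":
        return json.dumps(report_to_dict(report), indent=2, sort_keys=True)

    tables = {
        "Overall test performance": overall_table(report),
        "Dispatch priority vs EMS criteria crosstab": crosstab_table(report),
        "Per-category test performance": category_table(report),
    }
    if format == "csv":
        buf = io.StringIO()
        for title, df in tables.items():
            buf.write(f"# {title}\n")
            df.to_csv(buf, index=False)
        return buf.getvalue()
    if format == "text":
        buf = io.StringIO()
        for title, df in tables.items():
            buf.write(title + "\n")
            buf.write(df.to_string(index=False))
            buf.write("\n")
            for key in ("over_triage", "under_triage"):
                if key in df.attrs:
                    buf.write(f"{key.replace('_', '-').capitalize()}: {df.attrs[key]}\n")
            buf.write("\n")
        return buf.getvalue()
    raise ValueError(f"unknown format {format!r}")
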