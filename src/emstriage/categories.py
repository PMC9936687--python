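"""Per-dispatch-category summaries and cross-category statistics.

Each dispatch category (Chest pain, Fall, ...) gets its own confusion matrix
and metric suite.  Categories with more than ``min_n`` dispatches (default
50, strict: n = 51 qualifies, n = 50 does not) enter the formal comparisons:

* a Pearson chi-square test of association between dispatch priority and the
  reference-standard label;
* a Kruskal-Wallis H test on the per-record *consistency variable* — each
  record coded by its confusion cell (default TP=1, FP=2, TN=3, FN=4; the
  coding is a convention, exposed as a parameter) — grouped by category;
* Dunn's rank-based pairwise z-tests between categories with Bonferroni
  correction as the post hoc.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .metrics import (
    CiMethod,
    ConfusionCounts,
    MetricEstimate,
    build_confusion,
    compute_metrics,
    confusion_cell,
)
from .records import Urgency, normalize_category
from .reference_standard import ClassifiedRecord

DEFAULT_MIN_N = 50

#: default confusion-cell coding for the consistency variable
DEFAULT_CODING: dict[str, int] = {"TP": 1, "FP": 2, "TN": 3, "FN": 4}


class TestName(str, Enum):
    __test__ = False  # not a pytest class

    CHI_SQUARE = "chi_square"
    KRUSKAL_WALLIS = "kruskal_wallis"
    DUNN_PAIRWISE = "dunn_pairwise"


@dataclass(frozen=True)
class TestResult:
    test_name: TestName
    statistic: float
    p_value: float
    df: int | None = None
    adjusted_p: float | None = None
    groups: tuple[str, str] | None = None

    @property
    def significant(self) -> bool:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        return p < 0.05


@dataclass(frozen=True)
class CategorySummary:
    category: str
    n: int
    confusion: ConfusionCounts
    metrics: list[MetricEstimate]
    emd_urgent_n: int
    emd_non_urgent_n: int
    eligible_for_tests: bool


def summarize_by_category(
    classified: Sequence[ClassifiedRecord],
    min_n: int = DEFAULT_MIN_N,
    ci_method: CiMethod = "wald",
) -> list[CategorySummary]:
    """One summary per category, largest first; categories at or below
    ``min_n`` are summarised but flagged ineligible for the formal tests."""
    groups: dict[str, list[ClassifiedRecord]] = defaultdict(list)
    display: dict[str, str] = {}
    for cr in classified:
        key = normalize_category(cr.record.category)
        groups[key].append(cr)
        display.setdefault(key, cr.record.category.strip())

    out = []
    for key, crs in groups.items():
        confusion = build_confusion([(cr.emd_label, cr.ems_label) for cr in crs])
        emd_urgent = sum(cr.emd_label is Urgency.URGENT for cr in crs)
        out.append(
            CategorySummary(
                category=display[key],
                n=len(crs),
                confusion=confusion,
                metrics=compute_metrics(confusion, ci_method=ci_method),
                emd_urgent_n=emd_urgent,
                emd_non_urgent_n=len(crs) - emd_urgent,
                eligible_for_tests=len(crs) > min_n,
            )
        )
    out.sort(key=lambda s: (-s.n, s.category))
    return out


def chi_square_association(table: np.ndarray | Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has an empty row or column marginal")
    res = stats.chi2_contingency(arr, correction=False)
    return TestResult(
        TestName.CHI_SQUARE, statistic=float(res.statistic), p_value=float(res.pvalue), df=int(res.dof)
    )


def _consistency_groups(
    classified: Sequence[ClassifiedRecord],
    coding: Mapping[str, int],
    min_n: int,
) -> dict[str, np.ndarray]:
    if len(set(coding.values())) != len(coding):
        raise ValueError("consistency coding must be injective")
    scores: dict[str, list[int]] = defaultdict(list)
    for cr in classified:
        key = normalize_category(cr.record.category)
        scores[key].append(coding[confusion_cell(cr.emd_label, cr.ems_label)])
    return {k: np.asarray(v) for k, v in scores.items() if len(v) > min_n}


def kruskal_wallis_consistency(
    classified: Sequence[ClassifiedRecord],
    coding: Mapping[str, int] = DEFAULT_CODING,
    min_n: int = DEFAULT_MIN_N,
) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) on the coded consistency variable
    across eligible categories; df = number of eligible categories - 1."""
    groups = _consistency_groups(classified, coding, min_n)
    if len(groups) < 2:
        raise ValueError("need at least two categories above the size threshold")
    h, p = stats.kruskal(*groups.values())
    return TestResult(TestName.KRUSKAL_WALLIS, statistic=float(h), p_value=float(p), df=len(groups) - 1)


def pairwise_posthoc(
    classified: Sequence[ClassifiedRecord],
    coding: Mapping[str, int] = DEFAULT_CODING,
    min_n: int = DEFAULT_MIN_N,
) -> list[TestResult]:
    """Dunn's z-test on mean ranks for every unordered category pair, with
    Bonferroni-adjusted p-values (``adjusted_p = min(1, p * n_pairs)``).

    Uses the pooled ranking of all eligible records with the standard tie
    correction sum(t^3 - t) / (12 (N - 1)) subtracted from the rank variance.
    """
    groups = _consistency_groups(classified, coding, min_n)
    if len(groups) < 2:
        raise ValueError("need at least two categories above the size threshold")

    names = sorted(groups)
    pooled = np.concatenate([groups[n] for n in names])
    ranks = stats.rankdata(pooled)
    big_n = pooled.size

    mean_ranks: dict[str, float] = {}
    start = 0
    for n in names:
        size = groups[n].size
        mean_ranks[n] = float(ranks[start : start + size].mean())
        start += size

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (big_n - 1)))
    base_var = big_n * (big_n + 1) / 12.0 - tie_term

    pairs = list(combinations(names, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        results.append(
            TestResult(
                TestName.DUNN_PAIRWISE,
                statistic=float(z),
                p_value=p,
                adjusted_p=min(1.0, p * m),
                groups=(a, b),
            )
        )
    return results


def overall_confusion(summaries: Sequence[CategorySummary]) -> ConfusionCounts:
    """Sum of per-category confusion matrices (equals the register total)."""
    total = ConfusionCounts(0, 0, 0, 0)
    for s in summaries:
        total = total + s.confusion
    return total
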