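"""Triage test-performance metrics with binomial confidence intervals.

The dispatcher's dichotomised priority plays the role of the *test* and the
reference-standard EMS label the role of the *condition*: a dispatch is a
true positive when both sides call it urgent.  From the resulting 2x2
confusion counts the suite computes

    efficiency   = (TP + TN) / total          (overall concordance)
    sensitivity  = TP / (TP + FN)
    specificity  = TN / (TN + FP)
    PPV          = TP / (TP + FP)
    NPV          = TN / (TN + FN)
    over-triage  = 100 - PPV  (urgent dispatches that were not urgent on scene)
    under-triage = 100 - NPV  (non-urgent dispatches that were urgent on scene)

all as percentages with 95% confidence intervals.  The default interval is
the Wald normal approximation (z = 1.96), clamped to [0, 100]; the Wilson
score interval is selectable.  A metric whose denominator is empty is
undefined and rendered as ``N.A.``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Literal

from statsmodels.stats.proportion import proportion_confint

from .records import Urgency

Z_95 = 1.96

CiMethod = Literal["wald", "wilson"]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 cell counts. TP: both urgent; FP: dispatch urgent, scene
    non-urgent; TN: both non-urgent; FN: dispatch non-urgent, scene urgent."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion_cell(emd_label: Urgency, ems_label: Urgency) -> str:
    """Name of the cell a labelled pair falls into: TP, FP, TN or FN."""
    if emd_label is Urgency.URGENT:
        return "TP" if ems_label is Urgency.URGENT else "FP"
    return "FN" if ems_label is Urgency.URGENT else "TN"


def build_confusion(pairs: Iterable[tuple[Urgency, Urgency]]) -> ConfusionCounts:
    """Aggregate (dispatch label, scene label) pairs into confusion counts."""
    cells = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for emd, ems in pairs:
        cells[confusion_cell(emd, ems)] += 1
    return ConfusionCounts(cells["TP"], cells["FP"], cells["TN"], cells["FN"])


class MetricName(str, Enum):
    EFFICIENCY = "efficiency"
    SENSITIVITY = "sensitivity"
    SPECIFICITY = "specificity"
    PPV = "ppv"
    NPV = "npv"
    OVER_TRIAGE = "over_triage"
    UNDER_TRIAGE = "under_triage"


@dataclass(frozen=True)
class MetricEstimate:
    """A percentage point estimate with its binomial 95% CI and the counts it
    came from.  ``point_percent`` is None exactly when the denominator is
    zero (rendered ``N.A.``)."""

    name: MetricName
    numerator: int
    denominator: int
    point_percent: float | None
    ci_low_percent: float | None
    ci_high_percent: float | None
    z: float = Z_95

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def wald_ci(numerator: int, denominator: int, z: float = Z_95) -> tuple[float, float]:
    """Wald normal-approximation CI for a binomial proportion, in percent,
    clamped to [0, 100].  Undefined (ValueError) when the denominator is 0."""
    if denominator <= 0:
        raise ValueError("CI undefined for zero denominator")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    alpha = _alpha_from_z(z)
    low, high = proportion_confint(numerator, denominator, alpha=alpha, method="normal")
    return max(0.0, low * 100.0), min(100.0, high * 100.0)


def wilson_ci(numerator: int, denominator: int, z: float = Z_95) -> tuple[float, float]:
    """Wilson score interval, in percent."""
    if denominator <= 0:
        raise ValueError("CI undefined for zero denominator")
    alpha = _alpha_from_z(z)
    low, high = proportion_confint(numerator, denominator, alpha=alpha, method="wilson")
    return low * 100.0, high * 100.0


def _alpha_from_z(z: float) -> float:
    from scipy.stats import norm

    return 2.0 * norm.sf(z)


def _estimate(
    name: MetricName, num: int, den: int, ci_method: CiMethod, z: float
) -> MetricEstimate:
    if den == 0:
        return MetricEstimate(name, num, den, None, None, None, z)
    ci = wald_ci(num, den, z) if ci_method == "wald" else wilson_ci(num, den, z)
    return MetricEstimate(name, num, den, 100.0 * num / den, ci[0], ci[1], z)


def compute_metrics(
    c: ConfusionCounts, ci_method: CiMethod = "wald", z: float = Z_95
) -> list[MetricEstimate]:
    """All seven metrics for one confusion matrix, full precision.

    Over- and under-triage are the exact complements of PPV and NPV: their
    numerators are FP and FN over the same denominators, so the identities
    over + PPV = 100 and under + NPV = 100 hold before any rounding.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on an empty record set")
    return [
        _estimate(MetricName.EFFICIENCY, c.tp + c.tn, c.total, ci_method, z),
        _estimate(MetricName.SENSITIVITY, c.tp, c.tp + c.fn, ci_method, z),
        _estimate(MetricName.SPECIFICITY, c.tn, c.tn + c.fp, ci_method, z),
        _estimate(MetricName.PPV, c.tp, c.tp + c.fp, ci_method, z),
        _estimate(MetricName.NPV, c.tn, c.tn + c.fn, ci_method, z),
        _estimate(MetricName.OVER_TRIAGE, c.fp, c.tp + c.fp, ci_method, z),
        _estimate(MetricName.UNDER_TRIAGE, c.fn, c.tn + c.fn, ci_method, z),
    ]


def metrics_by_name(estimates: Iterable[MetricEstimate]) -> dict[MetricName, MetricEstimate]:
    return {e.name: e for e in estimates}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding, as report tables print (2.5 -> 3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(value: float | None, ndigits: int = 0) -> str:
    """Report-table rendering: half-up rounding, ``N.A.`` when undefined."""
    if value is None:
        return "N.A."
    r = round_half_up(value, ndigits)
    return f"{r:.{ndigits}f}" if ndigits else f"{int(r)}"
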