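#!/usr/bin/env python
"""Overall concordance between dispatch priority and on-scene urgency.

Runs the full pipeline on the simulated register and renders the overall
test-performance table and the 4x2 priority crosstab; for reference it also
prints the same metrics computed from the published crosstab cells, which is
the deterministic desk check the package's acceptance rests on.
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from emstriage.metrics import build_confusion, compute_metrics, metrics_by_name, format_percent
from emstriage.pipeline import crosstab_table, overall_table, run_pipeline
from emstriage.records import DispatchPriority, Urgency, dichotomise_emd
from emstriage.synthetic import REFERENCE_CROSSTAB

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    report = run_pipeline(SCRATCH / "synthetic_register.csv", run_posthoc=False)
    print("== synthetic register ==")
    print(overall_table(report).to_string(index=False))
    ct = crosstab_table(report)
    print(ct.to_string(index=False))
    print("Over-triage:", ct.attrs["over_triage"], "| Under-triage:", ct.attrs["under_triage"])
    overall_table(report).to_csv(OUT / "overall_metrics.csv", index=False)
    crosstab_table(report).to_csv(OUT / "crosstab.csv", index=False)

    pairs = []
    for letter, (n_u, n_nu) in REFERENCE_CROSSTAB.items():
        emd = dichotomise_emd(DispatchPriority(letter))
        pairs += [(emd, Urgency.URGENT)] * n_u + [(emd, Urgency.NON_URGENT)] * n_nu
    by_name = metrics_by_name(compute_metrics(build_confusion(pairs)))
    print("\n== published crosstab cells (desk check) ==")
    for name, e in by_name.items():
        print(
            f"  {name.value:13s} {format_percent(e.point_percent):>4s}%"
            f"  (95% CI {format_percent(e.ci_low_percent, 1)}-{format_percent(e.ci_high_percent, 1)})"
            f"  [{e.numerator}/{e.denominator}]"
        )


if __name__ == "__main__":
    main()
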