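#!/usr/bin/env python
"""Consistency across dispatch categories.

Per-category test-performance table (over-/under-triage, efficiency,
sensitivity, specificity, PPV, NPV), chi-square on the 4x2 crosstab,
Kruskal-Wallis H over the coded consistency variable among categories with
more than 50 dispatches, and Dunn's Bonferroni-corrected pairwise post hoc.
Writes the category table and the long-format pairwise results to results/.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from emstriage.categories import TestName
from emstriage.pipeline import category_table, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    report = run_pipeline(SCRATCH / "synthetic_register.csv")
    cat = category_table(report)
    cat.to_csv(OUT / "category_metrics.csv", index=False)
    print(cat.to_string(index=False))

    eligible = [s for s in report.categories if s.eligible_for_tests]
    print(f"\n{len(eligible)} categories above the >50 threshold")
    pairwise_rows = []
    for t in report.tests:
        if t.test_name is TestName.CHI_SQUARE:
            print(f"chi-square: stat={t.statistic:.1f}, df={t.df}, p={t.p_value:.3g}")
        elif t.test_name is TestName.KRUSKAL_WALLIS:
            print(f"Kruskal-Wallis H: stat={t.statistic:.1f}, df={t.df}, p={t.p_value:.3g}")
        else:
            pairwise_rows.append(
                {
                    "category_a": t.groups[0],
                    "category_b": t.groups[1],
                    "z": t.statistic,
                    "p_raw": t.p_value,
                    "p_bonferroni": t.adjusted_p,
                    "significant": t.significant,
                }
            )
    pw = pd.DataFrame(pairwise_rows)
    pw.to_csv(OUT / "pairwise_posthoc.csv", index=False)
    n_sig = int(pw["significant"].sum())
    print(f"post hoc: {len(pw)} pairwise comparisons, {n_sig} significant after Bonferroni")
    flagged = set(pw.loc[pw.significant, "category_a"]) | set(pw.loc[pw.significant, "category_b"])
    print(f"categories appearing in at least one significant pair: {len(flagged)}")


if __name__ == "__main__":
    main()
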