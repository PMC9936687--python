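#!/usr/bin/env python
"""Apply the reference-standard urgency criteria to the simulated register.

Reads results/synthetic_register.csv, drops the excluded dispatches, labels
every remaining record urgent/non-urgent on the EMS side, and writes the
audit table (record id, both labels, rule fired) plus the rule-firing
distribution, which shows how often the paramedic's own assessment versus
the transport/death/treatment criteria decided the label.
"""

from __future__ import annotations

import csv
import json
import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from emstriage.records import apply_exclusions, read_register
from emstriage.reference_standard import classify_register

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    records, report = read_register(SCRATCH / "synthetic_register.csv")
    if report.issues:
        print(f"parse issues: {len(report.issues)}")
    included = apply_exclusions(records).included
    classified = classify_register(included)

    with open(SCRATCH / "classified.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "emd_label", "ems_label", "rule_fired"])
        for cr in classified:
            w.writerow([cr.record.record_id, cr.emd_label.value, cr.ems_label.value, cr.trace.rule_fired.value])

    rules = Counter(cr.trace.rule_fired.value for cr in classified)
    (OUT / "rule_tally.json").write_text(json.dumps(dict(rules), indent=2, sort_keys=True))
    print(f"classified {len(classified)} dispatches; rule distribution:")
    for rule, n in rules.most_common():
        print(f"  {rule:30s} {n:5d}")


if __name__ == "__main__":
    main()
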