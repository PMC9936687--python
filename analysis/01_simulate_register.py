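#!/usr/bin/env python
"""Generate the synthetic dispatch register the downstream analyses use.

The generator emulates one month of EMS dispatches in a Finnish hospital
district: 26 real dispatch categories with their published sizes, dispatch-
priority splits and on-scene urgency frequencies, plus a tail of 29 small
categories standing in for the rarer codes.  Writes the register CSV and an
exclusion tally to results/.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from emstriage.records import apply_exclusions
from emstriage.synthetic import default_config, write_synthetic_register

SEED = 20230216
OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    cfg = default_config(seed=SEED)
    records = write_synthetic_register(cfg, SCRATCH / "synthetic_register.csv")
    res = apply_exclusions(records)
    print(f"generated {len(records)} dispatches (seed {SEED})")
    print(f"analysable: {len(res.included)}; excluded: {len(res.excluded)} by reason {dict(res.reasons)}")
    (OUT / "exclusions.json").write_text(
        json.dumps(
            {"n_total": len(records), "n_included": len(res.included), "reasons": dict(res.reasons)},
            indent=2,
        )
    )


if __name__ == "__main__":
    main()
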