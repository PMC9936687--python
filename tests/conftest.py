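"""Shared fixtures and record factories for the test suite."""

from __future__ import annotations

import pytest

from emstriage.records import (
    ClinicalObservations,
    DispatchPriority,
    DispatchRecord,
    Interventions,
    MissionStatus,
    ParamedicAssessment,
    TransportDisposition,
    Urgency,
    dichotomise_emd,
)
from emstriage.synthetic import (
    REFERENCE_CROSSTAB,
    default_config,
    generate_register_with_labels,
)


def make_record(
    record_id: str = "r1",
    category: str = "Chest pain",
    emd_priority: DispatchPriority = DispatchPriority.B,
    status: MissionStatus = MissionStatus.COMPLETED,
    transported: bool = False,
    transport_priority: DispatchPriority | None = None,
    paramedic: ParamedicAssessment = ParamedicAssessment.NOT_DOCUMENTED,
    obs: ClinicalObservations | None = None,
    ivx: Interventions | None = None,
) -> DispatchRecord:
    """A minimal completed record with everything defaulted to benign."""
    return DispatchRecord(
        record_id=record_id,
        category=category,
        emd_priority=emd_priority,
        status=status,
        disposition=TransportDisposition(transported, transport_priority),
        observations=obs or ClinicalObservations(),
        interventions=ivx or Interventions(),
        paramedic_assessment=paramedic,
    )


def crosstab_pairs() -> list[tuple[Urgency, Urgency]]:
    """(dispatch label, reference label) pairs reconstructed from the
    published priority-letter crosstab."""
    pairs = []
    for letter, (n_urgent, n_non_urgent) in REFERENCE_CROSSTAB.items():
        emd = dichotomise_emd(DispatchPriority(letter))
        pairs += [(emd, Urgency.URGENT)] * n_urgent
        pairs += [(emd, Urgency.NON_URGENT)] * n_non_urgent
    return pairs


def records_from_crosstab() -> list[DispatchRecord]:
    """A register whose classification reproduces the published crosstab
    exactly, using documented paramedic assessments as the reference label."""
    records = []
    i = 0
    for letter, (n_urgent, n_non_urgent) in REFERENCE_CROSSTAB.items():
        for ems, count in ((ParamedicAssessment.URGENT, n_urgent), (ParamedicAssessment.NON_URGENT, n_non_urgent)):
            for _ in range(count):
                records.append(
                    make_record(record_id=f"x{i}", emd_priority=DispatchPriority(letter), paramedic=ems)
                )
                i += 1
    return records


@pytest.fixture(scope="session")
def default_register():
    """One synthetic register at the study's scale, with latent labels."""
    cfg = default_config(seed=7)
    records, labels = generate_register_with_labels(cfg)
    return cfg, records, labels
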