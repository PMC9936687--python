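"""Rule-based reference standard for on-scene EMS urgency.

The reference standard labels every analysed dispatch urgent or non-urgent
from the crew's perspective, using pre-set criteria rather than a severity
score (Finnish paramedics do not routinely record NACA or METTS scores).
The paramedic's own documented assessment is primary; when it is absent the
label is derived from the transport priority, death on scene, and whether
the patient received *significant treatment* — one of eight
condition-plus-intervention conjunctions (e.g. SpO2 < 95 % treated with
bronchodilators, CPR, hypoglycaemia corrected with IV glucose).

Dichotomisation order for records without a documented assessment:

* lights-and-siren dispatch (A/B): urgent if transported with A/B priority,
  or deceased, or significant treatment given (regardless of transport);
  otherwise non-urgent;
* non-lights-and-siren dispatch (C/D): urgent if transported with A/B
  priority, or not transported but given significant treatment; otherwise
  non-urgent — including transported with C/D priority and deceased on
  scene.

An urgent A/B transport after a C/D dispatch counts as urgent (hence a
false negative for the dispatcher).  That reading is the default; the
alternative — treating such transports as non-urgent — is selectable with
``cd_ab_transport_urgent=False`` because the criteria table can be read
either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .records import (
    ClinicalObservations,
    DispatchPriority,
    DispatchRecord,
    Interventions,
    MissionStatus,
    ParamedicAssessment,
    Urgency,
    dichotomise_emd,
)

SPO2_THRESHOLD = 95.0  # %
GLUCOSE_THRESHOLD = 4.0  # mmol/L
SPCO_THRESHOLD = 5.0  # %


class Rule(str, Enum):
    """Identifier of the first criterion satisfied during classification."""

    PARAMEDIC_OVERRIDE = "paramedic_override"
    AB_TRANSPORT_AB = "ab_transport_ab"
    AB_DECEASED = "ab_deceased"
    AB_SIGNIFICANT_TREATMENT = "ab_significant_treatment"
    AB_DEFAULT_NON_URGENT = "ab_default_non_urgent"
    CD_TRANSPORT_AB = "cd_transport_ab"
    CD_TREATMENT_NO_TRANSPORT = "cd_treatment_no_transport"
    CD_DEFAULT_NON_URGENT = "cd_default_non_urgent"


@dataclass(frozen=True)
class ClassificationTrace:
    label: Urgency
    rule_fired: Rule
    significant_treatment: bool


class ContractViolation(RuntimeError):
    """A record outside the analysis set reached the classifier."""


def has_significant_treatment(obs: ClinicalObservations, ivx: Interventions) -> bool:
    """True iff at least one of the eight significant-treatment criteria holds.

    Each criterion pairs a condition with the treatment actually given:
    hypoxia (SpO2 < 95 %) with bronchodilators, convulsion with an
    anticonvulsant, allergic reaction with epinephrine, hypoglycaemia
    (glucose < 4 mmol/L) with IV glucose, carbon-monoxide exposure
    (SpCO > 5 %) with oxygen, poisoning/overdose with an antidote; airway
    management and CPR count unconditionally.  An unmeasured vital never
    satisfies its criterion.
    """
    if ivx.airway_management_performed or ivx.cpr_performed:
        return True
    if obs.spo2_percent is not None and obs.spo2_percent < SPO2_THRESHOLD and ivx.bronchodilator_given:
        return True
    if obs.convulsion_present and ivx.anticonvulsant_given:
        return True
    if obs.allergic_reaction_present and ivx.epinephrine_given:
        return True
    if (
        obs.blood_glucose_mmol_l is not None
        and obs.blood_glucose_mmol_l < GLUCOSE_THRESHOLD
        and ivx.iv_glucose_given
    ):
        return True
    if obs.spco_percent is not None and obs.spco_percent > SPCO_THRESHOLD and ivx.oxygen_given:
        return True
    if obs.overdose_or_poisoning_present and ivx.antidote_given:
        return True
    return False


def _transported_urgently(record: DispatchRecord) -> bool:
    d = record.disposition
    return d.transported and d.transport_priority in (DispatchPriority.A, DispatchPriority.B)


def classify_ems_urgency(
    record: DispatchRecord, *, cd_ab_transport_urgent: bool = True
) -> ClassificationTrace:
    """Apply the reference-standard criteria to one analysed record.

    Raises :class:`ContractViolation` for records that should have been
    excluded (mission not completed with patient confronted).
    """
    if record.status is not MissionStatus.COMPLETED:
        raise ContractViolation(
            f"record {record.record_id!r} has status {record.status.value}; "
            "only completed, patient-confronted dispatches are classifiable"
        )

    sig = has_significant_treatment(record.observations, record.interventions)

    if record.paramedic_assessment is not ParamedicAssessment.NOT_DOCUMENTED:
        label = (
            Urgency.URGENT
            if record.paramedic_assessment is ParamedicAssessment.URGENT
            else Urgency.NON_URGENT
        )
        return ClassificationTrace(label, Rule.PARAMEDIC_OVERRIDE, sig)

    if dichotomise_emd(record.emd_priority) is Urgency.URGENT:  # A/B dispatch
        if _transported_urgently(record):
            return ClassificationTrace(Urgency.URGENT, Rule.AB_TRANSPORT_AB, sig)
        if record.observations.deceased:
            return ClassificationTrace(Urgency.URGENT, Rule.AB_DECEASED, sig)
        if sig:
            return ClassificationTrace(Urgency.URGENT, Rule.AB_SIGNIFICANT_TREATMENT, sig)
        return ClassificationTrace(Urgency.NON_URGENT, Rule.AB_DEFAULT_NON_URGENT, sig)

    # C/D dispatch
    if cd_ab_transport_urgent and _transported_urgently(record):
        return ClassificationTrace(Urgency.URGENT, Rule.CD_TRANSPORT_AB, sig)
    if not record.disposition.transported and sig:
        return ClassificationTrace(Urgency.URGENT, Rule.CD_TREATMENT_NO_TRANSPORT, sig)
    return ClassificationTrace(Urgency.NON_URGENT, Rule.CD_DEFAULT_NON_URGENT, sig)


@dataclass(frozen=True)
class ClassifiedRecord:
    """A record with both sides of the comparison attached: the dispatcher's
    dichotomised priority and the reference-standard label."""

    record: DispatchRecord
    emd_label: Urgency
    ems_label: Urgency
    trace: ClassificationTrace


def classify_register(
    records: Iterable[DispatchRecord], *, cd_ab_transport_urgent: bool = True
) -> list[ClassifiedRecord]:
    """Classify every record of an analysis set on both sides."""
    out = []
    for r in records:
        trace = classify_ems_urgency(r, cd_ab_transport_urgent=cd_ab_transport_urgent)
        out.append(ClassifiedRecord(r, dichotomise_emd(r.emd_priority), trace.label, trace))
    return out
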