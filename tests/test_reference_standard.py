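"""Reference-standard urgency classification against independent oracles.

The oracle here is a flat, independent transcription of the urgency criteria
(a disjunction of condition-and-treatment conjunctions plus nested transport/
death rules), kept deliberately separate from the package's implementation.
"""

from __future__ import annotations

from itertools import product

import pytest
from hypothesis import given, settings, strategies as st

from emstriage.records import (
    ClinicalObservations,
    DispatchPriority,
    Interventions,
    MissionStatus,
    ParamedicAssessment,
    Urgency,
)
from emstriage.reference_standard import (
    ContractViolation,
    Rule,
    classify_ems_urgency,
    classify_register,
    has_significant_treatment,
)

from conftest import make_record

# --- independent oracle -----------------------------------------------------


def oracle_significant_treatment(obs: ClinicalObservations, ivx: Interventions) -> bool:
    return any(
        [
            obs.spo2_percent is not None and obs.spo2_percent < 95 and ivx.bronchodilator_given,
            obs.convulsion_present and ivx.anticonvulsant_given,
            obs.allergic_reaction_present and ivx.epinephrine_given,
            ivx.airway_management_performed,
            ivx.cpr_performed,
            obs.blood_glucose_mmol_l is not None and obs.blood_glucose_mmol_l < 4 and ivx.iv_glucose_given,
            obs.spco_percent is not None and obs.spco_percent > 5 and ivx.oxygen_given,
            obs.overdose_or_poisoning_present and ivx.antidote_given,
        ]
    )


def oracle_classify(record) -> Urgency:
    if record.paramedic_assessment is ParamedicAssessment.URGENT:
        return Urgency.URGENT
    if record.paramedic_assessment is ParamedicAssessment.NON_URGENT:
        return Urgency.NON_URGENT
    ab = record.emd_priority in (DispatchPriority.A, DispatchPriority.B)
    transported_ab = record.disposition.transported and record.disposition.transport_priority in (
        DispatchPriority.A,
        DispatchPriority.B,
    )
    sig = oracle_significant_treatment(record.observations, record.interventions)
    if ab:
        if transported_ab or record.observations.deceased or sig:
            return Urgency.URGENT
        return Urgency.NON_URGENT
    if transported_ab:
        return Urgency.URGENT
    if not record.disposition.transported and sig:
        return Urgency.URGENT
    return Urgency.NON_URGENT


# --- significant treatment --------------------------------------------------


def test_significant_treatment_truth_table_matches_oracle():
    """Exhaustive grid over all 2^8 intervention combinations at boundary
    vitals (94.9/95.0 SpO2, 3.99/4.0 glucose, 5.0/5.01 SpCO) and all
    condition flags."""
    spo2_vals = (None, 94.9, 95.0)
    glucose_vals = (None, 3.99, 4.0)
    spco_vals = (None, 5.0, 5.01)
    flags = (False, True)
    n_checked = 0
    for spo2, glu, spco, conv, alle, over in product(
        spo2_vals, glucose_vals, spco_vals, flags, flags, flags
    ):
        obs = ClinicalObservations(
            spo2_percent=spo2,
            blood_glucose_mmol_l=glu,
            spco_percent=spco,
            convulsion_present=conv,
            allergic_reaction_present=alle,
            overdose_or_poisoning_present=over,
        )
        for bits in product(flags, repeat=8):
            ivx = Interventions(*bits)
            assert has_significant_treatment(obs, ivx) == oracle_significant_treatment(obs, ivx)
            n_checked += 1
    assert n_checked == 3 * 3 * 3 * 2 * 2 * 2 * 256


@pytest.mark.parametrize(
    "obs, ivx, expected",
    [
        # hypoxia treated with bronchodilators is significant; untreated is not
        (ClinicalObservations(spo2_percent=92), Interventions(bronchodilator_given=True), True),
        (ClinicalObservations(spo2_percent=92), Interventions(), False),
        # CPR counts unconditionally
        (ClinicalObservations(), Interventions(cpr_performed=True), True),
        # unmeasured vital can never satisfy its criterion
        (ClinicalObservations(), Interventions(bronchodilator_given=True), False),
        # treatment without the qualifying condition does not count
        (ClinicalObservations(spo2_percent=96), Interventions(bronchodilator_given=True), False),
    ],
)
def test_significant_treatment_examples(obs, ivx, expected):
    assert has_significant_treatment(obs, ivx) is expected


# --- classification ---------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs, label, rule",
    [
        # documented crew assessment wins regardless of everything else
        (
            dict(emd_priority=DispatchPriority.C, paramedic=ParamedicAssessment.URGENT),
            Urgency.URGENT,
            Rule.PARAMEDIC_OVERRIDE,
        ),
        # urgent dispatch with urgent transport
        (
            dict(emd_priority=DispatchPriority.B, transported=True, transport_priority=DispatchPriority.A),
            Urgency.URGENT,
            Rule.AB_TRANSPORT_AB,
        ),
        # urgent dispatch downgraded on scene: routine transport, no treatment
        (
            dict(emd_priority=DispatchPriority.A, transported=True, transport_priority=DispatchPriority.C),
            Urgency.NON_URGENT,
            Rule.AB_DEFAULT_NON_URGENT,
        ),
        # death after a non-urgent dispatch is non-urgent
        (
            dict(emd_priority=DispatchPriority.C, obs=ClinicalObservations(deceased=True)),
            Urgency.NON_URGENT,
            Rule.CD_DEFAULT_NON_URGENT,
        ),
        # death after an urgent dispatch is urgent
        (
            dict(emd_priority=DispatchPriority.A, obs=ClinicalObservations(deceased=True)),
            Urgency.URGENT,
            Rule.AB_DECEASED,
        ),
        # non-urgent dispatch, treated on scene without transport
        (
            dict(
                emd_priority=DispatchPriority.D,
                obs=ClinicalObservations(allergic_reaction_present=True),
                ivx=Interventions(epinephrine_given=True),
            ),
            Urgency.URGENT,
            Rule.CD_TREATMENT_NO_TRANSPORT,
        ),
        # non-urgent dispatch escalated to urgent transport -> false negative
        (
            dict(emd_priority=DispatchPriority.C, transported=True, transport_priority=DispatchPriority.B),
            Urgency.URGENT,
            Rule.CD_TRANSPORT_AB,
        ),
        # non-urgent dispatch, routine transport despite treatment: literal
        # reading requires no transport for the treatment rule
        (
            dict(
                emd_priority=DispatchPriority.D,
                transported=True,
                transport_priority=DispatchPriority.D,
                obs=ClinicalObservations(spo2_percent=90),
                ivx=Interventions(bronchodilator_given=True),
            ),
            Urgency.NON_URGENT,
            Rule.CD_DEFAULT_NON_URGENT,
        ),
    ],
)
def test_classification_examples(kwargs, label, rule):
    trace = classify_ems_urgency(make_record(**kwargs))
    assert trace.label is label
    assert trace.rule_fired is rule


def test_classifier_matches_oracle_on_exhaustive_grid():
    """Every combination of paramedic assessment, dispatch letter, transport
    disposition, death and treatment agrees with the independent oracle."""
    transports = [(False, None)] + [(True, p) for p in DispatchPriority]
    treatments = [
        (ClinicalObservations(), Interventions()),
        (ClinicalObservations(spo2_percent=90), Interventions(bronchodilator_given=True)),
        (ClinicalObservations(), Interventions(cpr_performed=True)),
    ]
    n = 0
    for paramedic, emd, (transported, tp), deceased, (obs0, ivx) in product(
        ParamedicAssessment, DispatchPriority, transports, (False, True), treatments
    ):
        obs = ClinicalObservations(
            spo2_percent=obs0.spo2_percent,
            deceased=deceased,
        )
        record = make_record(
            emd_priority=emd, transported=transported, transport_priority=tp,
            paramedic=paramedic, obs=obs, ivx=ivx,
        )
        trace = classify_ems_urgency(record)
        assert trace.label is oracle_classify(record)
        n += 1
    assert n == 3 * 4 * 5 * 2 * 3


def test_alternative_reading_of_escalated_transport():
    record = make_record(
        emd_priority=DispatchPriority.C, transported=True, transport_priority=DispatchPriority.A
    )
    assert classify_ems_urgency(record).label is Urgency.URGENT
    assert (
        classify_ems_urgency(record, cd_ab_transport_urgent=False).label is Urgency.NON_URGENT
    )


def test_excluded_record_raises_contract_violation():
    record = make_record(status=MissionStatus.CANCELLED)
    with pytest.raises(ContractViolation, match="cancelled"):
        classify_ems_urgency(record)


def test_classify_register_is_total():
    records = [make_record(record_id=f"r{i}", emd_priority=p) for i, p in enumerate(DispatchPriority)]
    classified = classify_register(records)
    assert len(classified) == len(records)
    assert all(cr.ems_label in Urgency for cr in classified)


# --- property tests ---------------------------------------------------------

@st.composite
def record_strategy(draw):
    transported = draw(st.booleans())
    tp = draw(st.sampled_from(DispatchPriority)) if transported else None
    return make_record(
        emd_priority=draw(st.sampled_from(DispatchPriority)),
        transported=transported,
        transport_priority=tp,
        paramedic=draw(st.sampled_from(ParamedicAssessment)),
        obs=draw(
            st.builds(
                ClinicalObservations,
                spo2_percent=st.one_of(st.none(), st.floats(60, 100)),
                blood_glucose_mmol_l=st.one_of(st.none(), st.floats(1, 20)),
                spco_percent=st.one_of(st.none(), st.floats(0, 20)),
                deceased=st.booleans(),
                convulsion_present=st.booleans(),
                allergic_reaction_present=st.booleans(),
                overdose_or_poisoning_present=st.booleans(),
            )
        ),
        ivx=draw(st.builds(Interventions, *[st.booleans()] * 8)),
    )


@settings(max_examples=200, derandomize=True)
@given(record_strategy())
def test_random_records_match_oracle(record):
    assert classify_ems_urgency(record).label is oracle_classify(record)


@settings(max_examples=200, derandomize=True)
@given(record_strategy(), record_strategy())
def test_paramedic_assessment_is_primary(record, other):
    """With a documented assessment, no other field can change the label:
    swap in the disposition/observations/interventions of an arbitrary other
    record and the label must stay."""
    from dataclasses import replace

    if record.paramedic_assessment is ParamedicAssessment.NOT_DOCUMENTED:
        record = replace(record, paramedic_assessment=ParamedicAssessment.URGENT)
    mutated = replace(
        record,
        emd_priority=other.emd_priority,
        disposition=other.disposition,
        observations=other.observations,
        interventions=other.interventions,
    )
    assert classify_ems_urgency(mutated).label is classify_ems_urgency(record).label
    assert classify_ems_urgency(mutated).rule_fired is Rule.PARAMEDIC_OVERRIDE


@settings(max_examples=200, derandomize=True)
@given(record_strategy())
def test_adding_significant_treatment_is_monotone(record):
    """For undocumented records, adding a treated condition never turns an
    urgent label non-urgent."""
    from dataclasses import replace

    record = replace(record, paramedic_assessment=ParamedicAssessment.NOT_DOCUMENTED)
    before = classify_ems_urgency(record).label
    treated = replace(record, interventions=replace(record.interventions, cpr_performed=True))
    after = classify_ems_urgency(treated).label
    assert not (before is Urgency.URGENT and after is Urgency.NON_URGENT)
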