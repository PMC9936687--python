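"""Seeded generator of synthetic dispatch registers.

The real Finnish register this package analyses is not publicly available,
so the generator materialises a register with the same statistical
structure: the published per-category sizes, each category's dispatch-
priority split, and the conditional probability of an urgent reference-
standard label given the dispatched priority.  Records are generated
*latent-label first*: category, dichotomised dispatch priority and the
target on-scene label are sampled from those frequencies, then transport,
vitals and interventions are constructed to satisfy exactly one
reference-standard rule for that label, so classification provably recovers
the latent label for every included record.  This guarantees every rule
branch of the classifier is exercised and makes the pipeline's aggregate
statistics controllable.

The 26 published categories cover 6153 of the 6416 analysed dispatches; the
register also contained 29 rarer categories (263 dispatches) whose
per-category composition was not published.  These are emulated as 29 small
categories ("Other 01" ... "Other 29") sharing the aggregate confusion
composition that reconciles the published category table with the overall
crosstab, so the generator's expected overall confusion cells equal the
published overall counts (TP 688, FP 1653, TN 3949, FN 126 of 6416).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .records import (
    ClinicalObservations,
    DispatchPriority,
    DispatchRecord,
    EXCLUDED_STATUSES,
    Interventions,
    MissionStatus,
    ParamedicAssessment,
    TransportDisposition,
    Urgency,
    write_register,
)


@dataclass(frozen=True)
class CategoryFrequency:
    """Published composition of one dispatch category: size, urgent-dispatch
    count, and the four confusion cells (dispatch side vs reference side)."""

    name: str
    n: int
    emd_urgent: int
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if self.tp + self.fp != self.emd_urgent:
            raise ValueError(f"{self.name}: TP+FP must equal urgent-dispatch count")
        if self.tp + self.fp + self.tn + self.fn != self.n:
            raise ValueError(f"{self.name}: cells must sum to n")


#: Published per-category frequencies of the register the generator emulates
#: (the 26 categories with more than 50 dispatches, one month, 6416 analysed
#: dispatches in total).
REFERENCE_CATEGORIES: tuple[CategoryFrequency, ...] = (
    CategoryFrequency("General weakness", 984, 139, 26, 113, 827, 18),
    CategoryFrequency("Fall", 882, 159, 34, 125, 709, 14),
    CategoryFrequency("Chest pain", 631, 516, 105, 411, 110, 5),
    CategoryFrequency("Breathing difficulty", 407, 186, 53, 133, 211, 10),
    CategoryFrequency("Psychiatric symptom", 325, 0, 0, 0, 306, 19),
    CategoryFrequency("Rhythm disorder", 314, 83, 16, 67, 229, 2),
    CategoryFrequency("Stroke", 306, 250, 65, 185, 54, 2),
    CategoryFrequency("Abdominal pain", 286, 34, 11, 23, 247, 5),
    CategoryFrequency("Hospital transport", 253, 120, 84, 36, 117, 16),
    CategoryFrequency("Poisoning", 224, 84, 42, 42, 128, 12),
    CategoryFrequency("Back pain", 183, 9, 2, 7, 171, 3),
    CategoryFrequency("Limb pain", 144, 9, 2, 7, 134, 1),
    CategoryFrequency("Nausea, diarrhoea, constipation", 140, 3, 2, 1, 134, 3),
    CategoryFrequency("Convulsion", 137, 85, 31, 54, 50, 2),
    CategoryFrequency("Headache", 110, 46, 7, 39, 62, 2),
    CategoryFrequency("Traffic accident, bicycle etc.", 109, 44, 14, 30, 65, 0),
    CategoryFrequency("Unconscious", 99, 99, 42, 57, 0, 0),
    CategoryFrequency("Traffic accident, small", 97, 54, 9, 45, 42, 1),
    CategoryFrequency("Impact/hit", 76, 46, 9, 37, 30, 0),
    CategoryFrequency("Unspecific symptoms", 75, 75, 9, 66, 0, 0),
    CategoryFrequency("Blood glucose problem", 75, 19, 6, 13, 53, 3),
    CategoryFrequency("Cut", 67, 23, 7, 16, 44, 0),
    CategoryFrequency("Allergic reaction", 65, 45, 9, 36, 20, 0),
    CategoryFrequency("Body pain", 59, 4, 0, 4, 51, 4),
    CategoryFrequency("Assault", 54, 4, 0, 4, 50, 0),
    CategoryFrequency("Cardiac arrest", 51, 48, 44, 4, 3, 0),
)

#: Published overall crosstab: dispatch priority letter -> (reference urgent,
#: reference non-urgent) counts over the 6416 analysed dispatches.
REFERENCE_CROSSTAB: dict[str, tuple[int, int]] = {
    "A": (188, 153),
    "B": (500, 1500),
    "C": (99, 2161),
    "D": (27, 1788),
}

REFERENCE_N_ANALYSED = 6416
REFERENCE_N_EXCLUDED = 829
REFERENCE_N_TOTAL = REFERENCE_N_ANALYSED + REFERENCE_N_EXCLUDED

#: Aggregate composition of the 29 rarer categories: the difference between
#: the overall crosstab cells and the published-category column sums.
_REST_N_CATEGORIES = 29
_rest_tp = 688 - sum(c.tp for c in REFERENCE_CATEGORIES)
_rest_fp = 1653 - sum(c.fp for c in REFERENCE_CATEGORIES)
_rest_tn = 3949 - sum(c.tn for c in REFERENCE_CATEGORIES)
_rest_fn = 126 - sum(c.fn for c in REFERENCE_CATEGORIES)
_REST_TOTAL = _rest_tp + _rest_fp + _rest_tn + _rest_fn  # 263

_EmdKey = tuple[str, Urgency]


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic register.

    Probabilities are the register's published frequencies by default;
    ``a_within_ab`` and ``c_within_cd`` split the dichotomised priorities
    back into letters using the overall crosstab margins.  The paramedic
    documentation rate is a convention (documentation was voluntary and no
    rate was published).
    """

    n_dispatches: int = REFERENCE_N_TOTAL
    category_weights: dict[str, float] = field(default_factory=dict)
    emd_urgent_given_category: dict[str, float] = field(default_factory=dict)
    ems_urgent_given_category_and_emd: dict[_EmdKey, float] = field(default_factory=dict)
    paramedic_documentation_rate: float = 0.3
    exclusion_rate: float = REFERENCE_N_EXCLUDED / REFERENCE_N_TOTAL
    a_within_ab: float = 341 / 2341
    c_within_cd: float = 2260 / 4075
    seed: int = 0

    def validate(self) -> None:
        if self.n_dispatches <= 0:
            raise ValueError("n_dispatches must be positive")
        total_w = sum(self.category_weights.values())
        if abs(total_w - 1.0) > 1e-9:
            raise ValueError(f"category weights sum to {total_w}, expected 1")
        probs = (
            list(self.category_weights.values())
            + list(self.emd_urgent_given_category.values())
            + list(self.ems_urgent_given_category_and_emd.values())
            + [
                self.paramedic_documentation_rate,
                self.exclusion_rate,
                self.a_within_ab,
                self.c_within_cd,
            ]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_dispatches": self.n_dispatches,
            "category_weights": self.category_weights,
            "emd_urgent_given_category": self.emd_urgent_given_category,
            "ems_urgent_given_category_and_emd": {
                f"{cat}|{emd.value}": p
                for (cat, emd), p in self.ems_urgent_given_category_and_emd.items()
            },
            "paramedic_documentation_rate": self.paramedic_documentation_rate,
            "exclusion_rate": self.exclusion_rate,
            "a_within_ab": self.a_within_ab,
            "c_within_cd": self.c_within_cd,
            "seed": self.seed,
        }


def default_config(n_dispatches: int = REFERENCE_N_TOTAL, seed: int = 0) -> GeneratorConfig:
    """Generator configuration matching the published register frequencies.

    Category weights are proportional to published sizes (with the 263
    rare-category dispatches spread over 29 small "Other" categories);
    conditional urgency probabilities come from the published cells, so the
    expected overall confusion composition equals the published crosstab.
    """
    weights: dict[str, float] = {}
    p_emd: dict[str, float] = {}
    p_ems: dict[_EmdKey, float] = {}

    for c in REFERENCE_CATEGORIES:
        weights[c.name] = c.n / REFERENCE_N_ANALYSED
        p_emd[c.name] = c.emd_urgent / c.n
        p_ems[(c.name, Urgency.URGENT)] = c.tp / c.emd_urgent if c.emd_urgent else 0.0
        n_non = c.tn + c.fn
        p_ems[(c.name, Urgency.NON_URGENT)] = c.fn / n_non if n_non else 0.0

    rest_urgent = _rest_tp + _rest_fp
    rest_non = _rest_tn + _rest_fn
    sizes = [_REST_TOTAL // _REST_N_CATEGORIES] * _REST_N_CATEGORIES
    for i in range(_REST_TOTAL - sum(sizes)):
        sizes[i] += 1
    for i, size in enumerate(sizes, start=1):
        name = f"Other {i:02d}"
        weights[name] = size / REFERENCE_N_ANALYSED
        p_emd[name] = rest_urgent / _REST_TOTAL
        p_ems[(name, Urgency.URGENT)] = _rest_tp / rest_urgent
        p_ems[(name, Urgency.NON_URGENT)] = _rest_fn / rest_non

    cfg = GeneratorConfig(
        n_dispatches=n_dispatches,
        category_weights=weights,
        emd_urgent_given_category=p_emd,
        ems_urgent_given_category_and_emd=p_ems,
        seed=seed,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Record materialisation: construct fields that satisfy exactly one
# reference-standard rule for the sampled (dispatch stratum, label).

_NO_TRANSPORT = TransportDisposition(False, None)


def _normal_obs(rng: np.random.Generator) -> ClinicalObservations:
    """Vitals of a non-urgent encounter: mostly unmeasured, otherwise well
    inside the normal range; occasionally an abnormal vital *without* the
    corresponding treatment (which must not flip the label)."""
    u = rng.random()
    if u < 0.5:
        return ClinicalObservations()
    if u < 0.9:
        return ClinicalObservations(
            spo2_percent=float(rng.uniform(96.0, 100.0)),
            blood_glucose_mmol_l=float(rng.uniform(4.5, 9.0)),
        )
    return ClinicalObservations(spo2_percent=float(rng.uniform(90.0, 94.0)))


_TREATMENT_BUILDERS = (
    lambda rng: (
        ClinicalObservations(spo2_percent=float(rng.uniform(85.0, 92.0))),
        Interventions(bronchodilator_given=True),
    ),
    lambda rng: (
        ClinicalObservations(convulsion_present=True),
        Interventions(anticonvulsant_given=True),
    ),
    lambda rng: (
        ClinicalObservations(allergic_reaction_present=True),
        Interventions(epinephrine_given=True),
    ),
    lambda rng: (ClinicalObservations(), Interventions(airway_management_performed=True)),
    lambda rng: (ClinicalObservations(), Interventions(cpr_performed=True)),
    lambda rng: (
        ClinicalObservations(blood_glucose_mmol_l=float(rng.uniform(2.0, 3.5))),
        Interventions(iv_glucose_given=True),
    ),
    lambda rng: (
        ClinicalObservations(spco_percent=float(rng.uniform(6.0, 15.0))),
        Interventions(oxygen_given=True),
    ),
    lambda rng: (
        ClinicalObservations(overdose_or_poisoning_present=True),
        Interventions(antidote_given=True),
    ),
)


def _sample_treatment(rng: np.random.Generator) -> tuple[ClinicalObservations, Interventions]:
    return _TREATMENT_BUILDERS[rng.integers(len(_TREATMENT_BUILDERS))](rng)


def _transport(rng: np.random.Generator, letters: tuple[DispatchPriority, ...]) -> TransportDisposition:
    return TransportDisposition(True, letters[rng.integers(len(letters))])


_AB = (DispatchPriority.A, DispatchPriority.B)
_CD = (DispatchPriority.C, DispatchPriority.D)


def _materialise(
    rng: np.random.Generator, emd_label: Urgency, target: Urgency
) -> tuple[TransportDisposition, ClinicalObservations, Interventions]:
    """Fields satisfying exactly one reference-standard rule for the target
    label within the dispatch stratum, drawn uniformly over applicable rules."""
    if emd_label is Urgency.URGENT:  # A/B dispatch
        if target is Urgency.URGENT:
            rule = rng.integers(3)
            if rule == 0:  # urgent transport
                return _transport(rng, _AB), _normal_obs(rng), Interventions()
            if rule == 1:  # deceased on scene
                return _NO_TRANSPORT, ClinicalObservations(deceased=True), Interventions()
            # significant treatment, regardless of transport
            obs, ivx = _sample_treatment(rng)
            disp = _transport(rng, _CD) if rng.random() < 0.5 else _NO_TRANSPORT
            return disp, obs, ivx
        # A/B non-urgent: no urgent transport, alive, no significant treatment
        disp = _transport(rng, _CD) if rng.random() < 0.5 else _NO_TRANSPORT
        return disp, _normal_obs(rng), Interventions()

    # C/D dispatch
    if target is Urgency.URGENT:
        if rng.integers(2) == 0:  # escalated to urgent transport
            return _transport(rng, _AB), _normal_obs(rng), Interventions()
        obs, ivx = _sample_treatment(rng)  # treated on scene, not transported
        return _NO_TRANSPORT, obs, ivx
    # C/D non-urgent: routine transport, non-conveyance, or deceased
    rule = rng.integers(3)
    if rule == 0:
        return _transport(rng, _CD), _normal_obs(rng), Interventions()
    if rule == 1:
        return _NO_TRANSPORT, _normal_obs(rng), Interventions()
    return _NO_TRANSPORT, ClinicalObservations(deceased=True), Interventions()


_EXCLUDED_STATUS_LIST = tuple(sorted(EXCLUDED_STATUSES, key=lambda s: s.value))


def generate_register(config: GeneratorConfig) -> list[DispatchRecord]:
    """Generate a full synthetic register (included and excluded records).

    Deterministic for a fixed config and seed.  For every included record the
    reference-standard classification recovers the sampled latent label —
    either through the documented paramedic assessment or through the
    materialised fields.
    """
    return generate_register_with_labels(config)[0]


def generate_register_with_labels(
    config: GeneratorConfig,
) -> tuple[list[DispatchRecord], list[Urgency | None]]:
    """Like :func:`generate_register` but also returns the latent on-scene
    label per record (``None`` for excluded records), so the round-trip
    contract — classification recovers the latent label — is checkable."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = list(config.category_weights)
    weights = np.array([config.category_weights[n] for n in names])
    weights = weights / weights.sum()

    missing = [
        n
        for n in names
        if n not in config.emd_urgent_given_category
        or (n, Urgency.URGENT) not in config.ems_urgent_given_category_and_emd
        or (n, Urgency.NON_URGENT) not in config.ems_urgent_given_category_and_emd
    ]
    if missing:
        raise ValueError(f"no conditional probabilities configured for: {missing}")

    records: list[DispatchRecord] = []
    labels: list[Urgency | None] = []
    cat_idx = rng.choice(len(names), size=config.n_dispatches, p=weights)
    for i in range(config.n_dispatches):
        cat = names[cat_idx[i]]
        emd_label = (
            Urgency.URGENT
            if rng.random() < config.emd_urgent_given_category[cat]
            else Urgency.NON_URGENT
        )
        if emd_label is Urgency.URGENT:
            priority = (
                DispatchPriority.A if rng.random() < config.a_within_ab else DispatchPriority.B
            )
        else:
            priority = (
                DispatchPriority.C if rng.random() < config.c_within_cd else DispatchPriority.D
            )

        if rng.random() < config.exclusion_rate:
            status = _EXCLUDED_STATUS_LIST[rng.integers(len(_EXCLUDED_STATUS_LIST))]
            records.append(
                DispatchRecord(
                    record_id=f"SYN-{i:06d}",
                    category=cat,
                    emd_priority=priority,
                    status=status,
                    disposition=_NO_TRANSPORT,
                    observations=ClinicalObservations(),
                    interventions=Interventions(),
                )
            )
            labels.append(None)
            continue

        target = (
            Urgency.URGENT
            if rng.random() < config.ems_urgent_given_category_and_emd[(cat, emd_label)]
            else Urgency.NON_URGENT
        )
        documented = rng.random() < config.paramedic_documentation_rate
        disp, obs, ivx = _materialise(rng, emd_label, target)
        paramedic = (
            ParamedicAssessment(target.value) if documented else ParamedicAssessment.NOT_DOCUMENTED
        )
        records.append(
            DispatchRecord(
                record_id=f"SYN-{i:06d}",
                category=cat,
                emd_priority=priority,
                status=MissionStatus.COMPLETED,
                disposition=disp,
                observations=obs,
                interventions=ivx,
                paramedic_assessment=paramedic,
            )
        )
        labels.append(target)
    return records, labels


def write_synthetic_register(config: GeneratorConfig, path: str | Path) -> list[DispatchRecord]:
    """Generate and write a register CSV with a provenance header echoing the
    seed and configuration."""
    records = generate_register(config)
    comments = [
        "synthetic dispatch register (emstriage.synthetic)",
        f"seed={config.seed} n_dispatches={config.n_dispatches}",
        "config=" + json.dumps(config.to_dict(), sort_keys=True),
    ]
    write_register(records, path, header_comments=comments)
    return records
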