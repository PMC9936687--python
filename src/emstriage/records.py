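"""Dispatch-register data model, CSV I/O, validation and inclusion filtering.

A dispatch register holds one row per EMS dispatch: the dispatch category and
priority assigned by the emergency medical dispatcher (EMD) during the call,
the mission status, the transport disposition, on-scene clinical observations
and interventions, and the paramedic's optional urgency assessment.  Finnish
EMS uses four dispatch priorities: A (life-threatening) and B (urgent), both
lights-and-siren, versus C (semi-urgent, reach within 30 min) and D
(non-urgent, within 2 h).  For concordance analysis the four priorities are
dichotomised: A/B are urgent, C/D non-urgent.

Only dispatches where the crew confronted the patient enter the analysis;
cancelled, aborted, patient-not-confronted, first-responder and invalid-data
dispatches are excluded (but retained, so the exclusion tally is auditable).
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field, fields as dc_fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class DispatchPriority(str, Enum):
    """EMD dispatch priority letter. A/B imply lights-and-siren response."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"


class Urgency(str, Enum):
    """Binary urgency label used on both the EMD and the EMS side."""

    URGENT = "urgent"
    NON_URGENT = "non_urgent"


class MissionStatus(str, Enum):
    COMPLETED = "completed_patient_confronted"
    CANCELLED = "cancelled"
    ABORTED = "aborted"
    PATIENT_NOT_CONFRONTED = "patient_not_confronted"
    FIRST_RESPONDER = "first_responder"
    INVALID_DATA = "invalid_data"


#: statuses that remove a dispatch from the analysis set
EXCLUDED_STATUSES = frozenset(s for s in MissionStatus if s is not MissionStatus.COMPLETED)


class ParamedicAssessment(str, Enum):
    """The crew's own urgency call, documented on scene when the patient was
    confronted.  Documentation was voluntary, so ``NOT_DOCUMENTED`` is common.
    """

    URGENT = "urgent"
    NON_URGENT = "non_urgent"
    NOT_DOCUMENTED = "not_documented"


@dataclass(frozen=True)
class TransportDisposition:
    """Whether the patient was conveyed and, if so, under which priority."""

    transported: bool
    transport_priority: DispatchPriority | None = None

    def __post_init__(self) -> None:
        if self.transported and self.transport_priority is None:
            raise ValueError("transported record needs a transport_priority")
        if not self.transported and self.transport_priority is not None:
            raise ValueError("non-transported record cannot carry a transport_priority")


@dataclass(frozen=True)
class ClinicalObservations:
    """On-scene vitals and condition flags.  ``None`` means not measured,
    which is distinct from a normal or zero value: an unmeasured vital can
    never satisfy a treatment criterion.
    """

    spo2_percent: float | None = None
    blood_glucose_mmol_l: float | None = None
    spco_percent: float | None = None
    deceased: bool = False
    convulsion_present: bool = False
    allergic_reaction_present: bool = False
    overdose_or_poisoning_present: bool = False

    def __post_init__(self) -> None:
        if self.spo2_percent is not None and not 0 <= self.spo2_percent <= 100:
            raise ValueError(f"SpO2 out of [0,100]: {self.spo2_percent}")
        if self.blood_glucose_mmol_l is not None and self.blood_glucose_mmol_l < 0:
            raise ValueError("blood glucose must be non-negative")
        if self.spco_percent is not None and self.spco_percent < 0:
            raise ValueError("SpCO must be non-negative")


@dataclass(frozen=True)
class Interventions:
    """Treatments given on scene.  An empty source cell parses to False."""

    bronchodilator_given: bool = False
    anticonvulsant_given: bool = False
    epinephrine_given: bool = False
    airway_management_performed: bool = False
    cpr_performed: bool = False
    iv_glucose_given: bool = False
    oxygen_given: bool = False
    antidote_given: bool = False


@dataclass(frozen=True)
class DispatchRecord:
    record_id: str
    category: str
    emd_priority: DispatchPriority
    status: MissionStatus
    disposition: TransportDisposition
    observations: ClinicalObservations
    interventions: Interventions
    paramedic_assessment: ParamedicAssessment = ParamedicAssessment.NOT_DOCUMENTED


_WS = re.compile(r"\s+")

#: the register names the same category inconsistently across its tables
_CATEGORY_ALIASES = {"hospital transfer": "hospital transport"}


def normalize_category(label: str) -> str:
    """Canonical form of a dispatch-category label: whitespace collapsed,
    case-insensitive, with known alias spellings folded together."""
    canon = _WS.sub(" ", label.strip()).lower()
    return _CATEGORY_ALIASES.get(canon, canon)


def dichotomise_emd(priority: DispatchPriority) -> Urgency:
    """Collapse the four dispatch priorities to the binary urgency scale:
    A and B are urgent, C and D non-urgent."""
    if priority in (DispatchPriority.A, DispatchPriority.B):
        return Urgency.URGENT
    return Urgency.NON_URGENT


# ---------------------------------------------------------------------------
# CSV schema and parsing


#: logical field -> default CSV column name.  A custom mapping with the same
#: keys adapts a local register export.
DEFAULT_SCHEMA: dict[str, str] = {
    "record_id": "record_id",
    "category": "category",
    "emd_priority": "emd_priority",
    "status": "status",
    "transported": "transported",
    "transport_priority": "transport_priority",
    "spo2_percent": "spo2_percent",
    "blood_glucose_mmol_l": "blood_glucose_mmol_l",
    "spco_percent": "spco_percent",
    "deceased": "deceased",
    "convulsion_present": "convulsion_present",
    "allergic_reaction_present": "allergic_reaction_present",
    "overdose_or_poisoning_present": "overdose_or_poisoning_present",
    "bronchodilator_given": "bronchodilator_given",
    "anticonvulsant_given": "anticonvulsant_given",
    "epinephrine_given": "epinephrine_given",
    "airway_management_performed": "airway_management_performed",
    "cpr_performed": "cpr_performed",
    "iv_glucose_given": "iv_glucose_given",
    "oxygen_given": "oxygen_given",
    "antidote_given": "antidote_given",
    "paramedic_assessment": "paramedic_assessment",
}

_MANDATORY_FIELDS = ("record_id", "category", "emd_priority", "status", "transported")

_INTERVENTION_FIELDS = tuple(f.name for f in dc_fields(Interventions))

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f", ""}


class SchemaError(ValueError):
    """A mandatory column is missing from the file header."""


@dataclass(frozen=True)
class ParseIssue:
    row: int  # 1-based data-row number (header not counted)
    field: str
    reason: str


@dataclass
class ParseReport:
    issues: list[ParseIssue] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, row: int, field_name: str, reason: str) -> None:
        self.issues.append(ParseIssue(row, field_name, reason))

    @property
    def invalid_rows(self) -> set[int]:
        return {i.row for i in self.issues}

    def to_dict(self) -> dict:
        return {
            "issues": [vars(i) for i in self.issues],
            "warnings": list(self.warnings),
        }


def _parse_bool(token: str, row: int, name: str, report: ParseReport) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    report.add(row, name, f"unrecognised boolean token {token!r}")
    return False


def _parse_float(token: str, row: int, name: str, report: ParseReport) -> float | None:
    t = token.strip()
    if t == "":
        return None
    try:
        return float(t)
    except ValueError:
        report.add(row, name, f"not a number: {token!r}")
        return None


def _parse_enum(token: str, enum_cls, row: int, name: str, report: ParseReport):
    t = token.strip()
    try:
        return enum_cls(t.upper() if enum_cls is DispatchPriority else t.lower())
    except ValueError:
        report.add(row, name, f"invalid {enum_cls.__name__} token {token!r}")
        return None


def read_register(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[DispatchRecord], ParseReport]:
    """Read a dispatch register from CSV.

    Rows that fail validation are *kept* with status ``invalid_data`` and the
    failure is logged in the parse report, so downstream exclusion counts stay
    auditable.  Lines starting with ``#`` (provenance header comments written
    by the generator) are skipped.

    Raises :class:`SchemaError` if a mandatory mapped column is absent.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    report = ParseReport()
    records: list[DispatchRecord] = []

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(line for line in fh if not line.startswith("#"))
        if not reader.fieldnames:  # no header, or a blank first line
            report.warnings.append("empty file: no header row")
            return records, report
        header = set(reader.fieldnames)
        for logical in _MANDATORY_FIELDS:
            if schema[logical] not in header:
                raise SchemaError(f"mandatory column {schema[logical]!r} (field {logical!r}) missing")

        for i, row in enumerate(reader, start=1):
            records.append(_parse_row(row, i, schema, report))

    return records, report


def _parse_row(row: Mapping[str, str], i: int, schema: Mapping[str, str], report: ParseReport) -> DispatchRecord:
    def get(logical: str) -> str:
        return (row.get(schema[logical]) or "").strip()

    n_before = len(report.issues)

    record_id = get("record_id") or f"row-{i}"
    if not get("record_id"):
        report.add(i, "record_id", "missing record_id")
    category = get("category")
    if not category:
        report.add(i, "category", "missing category")

    emd = _parse_enum(get("emd_priority"), DispatchPriority, i, "emd_priority", report)
    status_tok = get("status") or MissionStatus.COMPLETED.value
    try:
        status = MissionStatus(status_tok.lower())
    except ValueError:
        report.add(i, "status", f"invalid status token {status_tok!r}")
        status = MissionStatus.INVALID_DATA

    transported = _parse_bool(get("transported"), i, "transported", report)
    tp_tok = get("transport_priority")
    transport_priority = None
    if tp_tok:
        transport_priority = _parse_enum(tp_tok, DispatchPriority, i, "transport_priority", report)
    if transported and transport_priority is None:
        report.add(i, "transport_priority", "transported without a transport priority")
        transported = False
    if not transported:
        transport_priority = None

    obs_kwargs = {
        "spo2_percent": _parse_float(get("spo2_percent"), i, "spo2_percent", report),
        "blood_glucose_mmol_l": _parse_float(get("blood_glucose_mmol_l"), i, "blood_glucose_mmol_l", report),
        "spco_percent": _parse_float(get("spco_percent"), i, "spco_percent", report),
        "deceased": _parse_bool(get("deceased"), i, "deceased", report),
        "convulsion_present": _parse_bool(get("convulsion_present"), i, "convulsion_present", report),
        "allergic_reaction_present": _parse_bool(get("allergic_reaction_present"), i, "allergic_reaction_present", report),
        "overdose_or_poisoning_present": _parse_bool(get("overdose_or_poisoning_present"), i, "overdose_or_poisoning_present", report),
    }
    try:
        observations = ClinicalObservations(**obs_kwargs)
    except ValueError as exc:
        report.add(i, "observations", str(exc))
        observations = ClinicalObservations(deceased=obs_kwargs["deceased"])

    interventions = Interventions(
        **{name: _parse_bool(get(name), i, name, report) for name in _INTERVENTION_FIELDS}
    )

    pa_tok = get("paramedic_assessment")
    if pa_tok == "":
        paramedic = ParamedicAssessment.NOT_DOCUMENTED
    else:
        try:
            paramedic = ParamedicAssessment(pa_tok.lower())
        except ValueError:
            report.add(i, "paramedic_assessment", f"invalid assessment token {pa_tok!r}")
            paramedic = ParamedicAssessment.NOT_DOCUMENTED

    if len(report.issues) > n_before or emd is None:
        status = MissionStatus.INVALID_DATA

    return DispatchRecord(
        record_id=record_id,
        category=category,
        emd_priority=emd if emd is not None else DispatchPriority.D,
        status=status,
        disposition=TransportDisposition(transported, transport_priority),
        observations=observations,
        interventions=interventions,
        paramedic_assessment=paramedic,
    )


def _fmt_bool(b: bool) -> str:
    return "1" if b else "0"


def _fmt_float(x: float | None) -> str:
    if x is None:
        return ""
    return repr(x)


def write_register(
    records: Iterable[DispatchRecord],
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    header_comments: Sequence[str] = (),
) -> None:
    """Write records to CSV in the same schema :func:`read_register` reads.

    ``header_comments`` lines are emitted before the header prefixed by ``#``
    (used by the generator to echo its seed and configuration)."""
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    cols = [schema[k] for k in DEFAULT_SCHEMA]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            obs, ivx = r.observations, r.interventions
            writer.writerow(
                [
                    r.record_id,
                    r.category,
                    r.emd_priority.value,
                    r.status.value,
                    _fmt_bool(r.disposition.transported),
                    r.disposition.transport_priority.value if r.disposition.transport_priority else "",
                    _fmt_float(obs.spo2_percent),
                    _fmt_float(obs.blood_glucose_mmol_l),
                    _fmt_float(obs.spco_percent),
                    _fmt_bool(obs.deceased),
                    _fmt_bool(obs.convulsion_present),
                    _fmt_bool(obs.allergic_reaction_present),
                    _fmt_bool(obs.overdose_or_poisoning_present),
                    *[_fmt_bool(getattr(ivx, name)) for name in _INTERVENTION_FIELDS],
                    "" if r.paramedic_assessment is ParamedicAssessment.NOT_DOCUMENTED else r.paramedic_assessment.value,
                ]
            )


@dataclass
class ExclusionResult:
    included: list[DispatchRecord]
    excluded: list[DispatchRecord]
    reasons: Counter

    def __iter__(self):  # allow ``included, excluded = apply_exclusions(...)``
        return iter((self.included, self.excluded))


def apply_exclusions(records: Sequence[DispatchRecord]) -> ExclusionResult:
    """Partition records into the analysis set and the excluded set.

    A record is analysable only when the mission completed with the patient
    confronted.  The partition is total: nothing is lost or duplicated, and
    exclusion reasons are tallied per status.
    """
    included, excluded = [], []
    reasons: Counter = Counter()
    for r in records:
        if r.status is MissionStatus.COMPLETED:
            included.append(r)
        else:
            excluded.append(r)
            reasons[r.status.value] += 1
    return ExclusionResult(included, excluded, reasons)
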