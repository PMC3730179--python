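"""Typed event-graph model of a patient history.

A *chronicle* is a semantic network built from a patient's record: clinical
events (investigations, interventions, diagnoses, prescriptions, clinical
problems) joined by typed directed relations.  Relations carry the story of
the illness — an investigation *infers* a problem (a biopsy reveals cancer),
a problem *causes* an intervention (cancer leads to chemotherapy), one event
*elaborates* or temporally *follows* another.  The whole report-generation
pipeline consumes this model.

Field-level constraints (closed event-class set, non-empty subtype, valid
calendar parts, interval ordering) are enforced at construction time by
pydantic; graph-level invariants (unique ids, resolvable endpoints, no
causal/inferential cycles) are checked by :func:`validate_chronicle`, which
reports violations rather than raising, so a malformed file can be
diagnosed in full.
"""

from __future__ import annotations

import enum
from typing import Any, Optional

import networkx as nx
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_validator,
    model_serializer,
    model_validator,
)

__all__ = [
    "EventClass",
    "RelationType",
    "ReportKind",
    "PartialDate",
    "DateSpan",
    "Event",
    "Relation",
    "Chronicle",
    "FocusSpec",
    "ReportRequest",
    "Violation",
    "validate_chronicle",
    "CLASS_ORDER",
]


class EventClass(str, enum.Enum):
    """Closed set of clinical event classes.

    Realisation rules key on the class; lexical choice keys on the open
    ``subtype`` vocabulary ("biopsy", "CT scan", "chemotherapy course", ...).
    """

    DIAGNOSIS = "Diagnosis"
    INVESTIGATION = "Investigation"
    INTERVENTION = "Intervention"
    PRESCRIPTION = "Prescription"
    CLINICAL_PROBLEM = "ClinicalProblem"


#: Fixed presentation order for same-date blocks in longitudinal reports.
CLASS_ORDER: tuple[EventClass, ...] = (
    EventClass.DIAGNOSIS,
    EventClass.INVESTIGATION,
    EventClass.INTERVENTION,
    EventClass.PRESCRIPTION,
    EventClass.CLINICAL_PROBLEM,
)

_CLASS_RANK = {c: i for i, c in enumerate(CLASS_ORDER)}


class RelationType(str, enum.Enum):
    INFERENCE = "inference"  # an event led to (revealed) another
    CAUSE = "cause"          # an event causes another
    ELABORATION = "elaboration"
    FOLLOWS = "follows"      # temporal sequencing


class ReportKind(str, enum.Enum):
    LONGITUDINAL = "longitudinal"
    PERSPECTIVE = "perspective"
    USER_DEFINED = "user_defined"


_MONTHS = (31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


class PartialDate(BaseModel):
    """A calendar date at day or month precision, year optional.

    Clinical narratives often date events only to the month, and extracted
    examples may omit the year entirely; precision is therefore explicit.
    Serialises as ``{"date": "<iso>", "precision": "day"|"month"}`` where the
    ISO form is ``YYYY-MM-DD``/``YYYY-MM`` or the year-truncated
    ``--MM-DD``/``--MM``.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    year: Optional[int] = Field(default=None, ge=1, le=9999)
    month: int = Field(ge=1, le=12)
    day: Optional[int] = Field(default=None, ge=1, le=31)

    @model_validator(mode="before")
    @classmethod
    def _accept_iso(cls, value: Any) -> Any:
        if isinstance(value, dict) and "date" in value:
            parsed = _parse_iso(str(value["date"]))
            precision = value.get("precision")
            if precision is not None and precision != parsed["precision"]:
                raise ValueError(
                    f"precision {precision!r} contradicts date {value['date']!r}"
                )
            parsed.pop("precision")
            return parsed
        if isinstance(value, str):
            parsed = _parse_iso(value)
            parsed.pop("precision")
            return parsed
        return value

    @model_validator(mode="after")
    def _check_day(self) -> "PartialDate":
        if self.day is not None and self.day > _MONTHS[self.month - 1]:
            raise ValueError(f"day {self.day} out of range for month {self.month}")
        return self

    @model_serializer
    def _to_json(self) -> dict[str, str]:
        return {"date": self.isoformat(), "precision": self.precision}

    @property
    def precision(self) -> str:
        return "day" if self.day is not None else "month"

    def isoformat(self) -> str:
        head = f"{self.year:04d}" if self.year is not None else "-"
        text = f"{head}-{self.month:02d}"
        if self.day is not None:
            text += f"-{self.day:02d}"
        return text

    def sort_key(self) -> tuple[int, int, int]:
        # Year-less dates sort first; month precision sorts before any day
        # of the same month.
        return (self.year or 0, self.month, self.day or 0)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


def _parse_iso(text: str) -> dict[str, Any]:
    """Parse ``YYYY-MM[-DD]`` or the year-truncated ``--MM[-DD]``."""
    year: Optional[int]
    if text.startswith("--"):
        year, rest = None, text[2:]
    else:
        head, _, rest = text.partition("-")
        if not head.isdigit() or not rest:
            raise ValueError(f"not an ISO date: {text!r}")
        year = int(head)
    parts = rest.split("-")
    if len(parts) == 1:
        month, day = int(parts[0]), None
    elif len(parts) == 2:
        month, day = int(parts[0]), int(parts[1])
    else:
        raise ValueError(f"not an ISO date: {text!r}")
    return {
        "year": year,
        "month": month,
        "day": day,
        "precision": "day" if day is not None else "month",
    }


class DateSpan(BaseModel):
    """A point date or an interval; ``end`` is absent for point events."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    start: PartialDate
    end: Optional[PartialDate] = None

    @model_validator(mode="after")
    def _ordered(self) -> "DateSpan":
        if self.end is not None and self.end.sort_key() < self.start.sort_key():
            raise ValueError("interval end precedes start")
        return self


class Event(BaseModel):
    """One clinical occurrence.

    ``attributes`` is an open feature map; the realiser understands ``locus``
    (anatomical site, rendered as a post-modifier), ``label`` (rendered as a
    parenthetical, e.g. a chemotherapy-course code) and ``content``.
    Missing ``time`` is allowed: such events are excluded from chronological
    ordering in their own right and rendered without a date phrase.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    id: str = Field(min_length=1)
    event_class: EventClass
    subtype: str = Field(min_length=1)
    attributes: dict[str, str] = Field(default_factory=dict)
    time: Optional[DateSpan] = None

    @field_validator("subtype")
    @classmethod
    def _subtype_nonblank(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("subtype must be non-empty")
        return v

    @property
    def class_rank(self) -> int:
        return _CLASS_RANK[self.event_class]

    @property
    def start_date(self) -> Optional[PartialDate]:
        return self.time.start if self.time is not None else None


class Relation(BaseModel):
    """Typed directed edge between two events (by id)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    source: str = Field(min_length=1)
    target: str = Field(min_length=1)
    relation_type: RelationType

    def key(self) -> tuple[str, str, str]:
        return (self.relation_type.value, self.source, self.target)


class Chronicle(BaseModel):
    """A patient's full event graph plus minimal metadata."""

    model_config = ConfigDict(extra="forbid")

    patient_id: str = Field(default="unknown", min_length=1)
    events: list[Event] = Field(default_factory=list)
    relations: list[Relation] = Field(default_factory=list)

    def events_by_id(self) -> dict[str, Event]:
        return {e.id: e for e in self.events}

    def get_event(self, event_id: str) -> Event:
        for e in self.events:
            if e.id == event_id:
                return e
        raise KeyError(event_id)


class FocusSpec(BaseModel):
    """One (event_class, optional subtype) focus criterion."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    event_class: EventClass
    subtype: Optional[str] = None

    def matches(self, event: Event) -> bool:
        if event.event_class is not self.event_class:
            return False
        return self.subtype is None or event.subtype == self.subtype


class ReportRequest(BaseModel):
    """User instructions for one report.

    ``depth`` bounds how many relation hops away from a spine event an
    elaborating event may lie; depth 0 lists the focused events alone.
    """

    model_config = ConfigDict(extra="forbid")

    kind: ReportKind
    focus_classes: list[FocusSpec] = Field(default_factory=list)
    depth: int = Field(default=1, ge=0)
    period: Optional[DateSpan] = None

    @model_validator(mode="after")
    def _focus_consistent(self) -> "ReportRequest":
        if self.kind is ReportKind.PERSPECTIVE:
            classes = {f.event_class for f in self.focus_classes}
            if len(classes) != 1:
                raise ValueError("perspective requests name exactly one event class")
        return self


class Violation(BaseModel):
    """One broken invariant, naming the offending entity and rule."""

    model_config = ConfigDict(frozen=True)

    rule: str
    entity: str
    message: str

    def __str__(self) -> str:
        return f"[{self.rule}] {self.entity}: {self.message}"


def validate_chronicle(chronicle: Chronicle) -> list[Violation]:
    """Check all graph-level invariants; return violations (empty if valid).

    Idempotent and side-effect free.  Checks: unique event ids, non-dangling
    relation endpoints, no self-relations, at most one relation per
    (type, source, target), and acyclicity of the cause/inference subgraph.
    Field-level invariants are normally guaranteed by construction but are
    re-checked defensively.
    """
    violations: list[Violation] = []

    seen: dict[str, int] = {}
    for event in chronicle.events:
        seen[event.id] = seen.get(event.id, 0) + 1
        if not event.subtype.strip():
            violations.append(
                Violation(rule="subtype", entity=event.id, message="empty subtype")
            )
        if (
            event.time is not None
            and event.time.end is not None
            and event.time.end.sort_key() < event.time.start.sort_key()
        ):
            violations.append(
                Violation(
                    rule="interval-order",
                    entity=event.id,
                    message="interval end precedes start",
                )
            )
    for event_id, count in seen.items():
        if count > 1:
            violations.append(
                Violation(
                    rule="duplicate-id",
                    entity=event_id,
                    message=f"event id occurs {count} times",
                )
            )

    ids = set(seen)
    rel_keys: dict[tuple[str, str, str], int] = {}
    for rel in chronicle.relations:
        name = f"{rel.relation_type.value}({rel.source}, {rel.target})"
        for endpoint in (rel.source, rel.target):
            if endpoint not in ids:
                violations.append(
                    Violation(
                        rule="dangling-endpoint",
                        entity=name,
                        message=f"references unknown event {endpoint!r}",
                    )
                )
        if rel.source == rel.target:
            violations.append(
                Violation(rule="self-relation", entity=name, message="source equals target")
            )
        rel_keys[rel.key()] = rel_keys.get(rel.key(), 0) + 1
    for key, count in rel_keys.items():
        if count > 1:
            violations.append(
                Violation(
                    rule="duplicate-relation",
                    entity=f"{key[0]}({key[1]}, {key[2]})",
                    message=f"relation occurs {count} times",
                )
            )

    causal = nx.DiGraph()
    causal.add_nodes_from(ids)
    for rel in chronicle.relations:
        if rel.relation_type in (RelationType.INFERENCE, RelationType.CAUSE):
            if rel.source in ids and rel.target in ids and rel.source != rel.target:
                causal.add_edge(rel.source, rel.target)
    for component in nx.strongly_connected_components(causal):
        if len(component) > 1:
            members = ", ".join(sorted(component))
            violations.append(
                Violation(
                    rule="causal-cycle",
                    entity=members,
                    message="cause/inference subgraph contains a cycle",
                )
            )

    return violations
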