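"""Microplanning: deciding *how* the selected content will be said.

Three jobs happen here.  Domain relations are mapped to generic rhetorical
relations (inference → result, cause → cause, elaboration → elaboration,
follows → sequence) so the realiser only ever deals in discourse-level
vocabulary.  Repeated events of the same kind are aggregated into a single
mention — strictly conceptual aggregation: only runs with an identical
(event class, subtype) merge, never two different subtypes under a broader
label.  Finally the content is distributed over paragraphs and sentences:
one paragraph per (possibly aggregated) spine entry, with a spine event and
a single directly linked elaboration packed into one sentence through their
rhetorical link, and at most one link per sentence.

Every selected event is *introduced* by exactly one message; rhetorical
links may additionally carry reference mentions of already-introduced
events, which the realiser renders as definite noun phrases ("the cancer").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

from .model import Chronicle, Event, PartialDate, Relation, RelationType
from .selection import ContentGraph, effective_dates, order_event_ids

__all__ = [
    "RST_CAUSE",
    "RST_RESULT",
    "RST_ELABORATION",
    "RST_SEQUENCE",
    "Message",
    "RhetoricalLink",
    "Paragraph",
    "DocumentPlan",
    "map_relation",
    "aggregate",
    "plan_document",
]

RST_CAUSE = "cause"
RST_RESULT = "result"
RST_ELABORATION = "elaboration"
RST_SEQUENCE = "sequence"

_RST_MAP: dict[RelationType, str] = {
    RelationType.INFERENCE: RST_RESULT,
    RelationType.CAUSE: RST_CAUSE,
    RelationType.ELABORATION: RST_ELABORATION,
    RelationType.FOLLOWS: RST_SEQUENCE,
}


def map_relation(relation_type: RelationType) -> str:
    """Fixed total mapping from domain relation types to RST relations."""
    try:
        return _RST_MAP[RelationType(relation_type)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown relation type: {relation_type!r}") from exc


@dataclass(frozen=True)
class Message:
    """One mention: a single event, or an aggregated run of similar events."""

    kind: str  # "event_mention" | "aggregated_mention"
    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        if self.kind == "aggregated_mention":
            if len(self.events) < 2:
                raise ValueError("aggregated_mention needs at least two events")
            keys = {(e.event_class, e.subtype) for e in self.events}
            if len(keys) != 1:
                raise ValueError("aggregated events must share class and subtype")
        elif self.kind == "event_mention":
            if len(self.events) != 1:
                raise ValueError("event_mention holds exactly one event")
        else:
            raise ValueError(f"unknown message kind: {self.kind}")

    @property
    def event_ids(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.events)

    @property
    def dates(self) -> tuple[PartialDate, ...]:
        return tuple(e.start_date for e in self.events if e.start_date is not None)


def mention(event: Event) -> Message:
    return Message(kind="event_mention", events=(event,))


@dataclass(frozen=True)
class RhetoricalLink:
    """Nucleus and satellite joined by a generic rhetorical relation.

    For *result* the nucleus is the revealing event (the investigation) and
    the satellite the revealed one; for *cause* the nucleus is the effect
    (the treatment clause) and the satellite the causing problem.
    """

    rst_relation: str
    nucleus: Message
    satellite: Message
    relation: Relation  # provenance: the domain edge this realises

    def __post_init__(self) -> None:
        if self.rst_relation != map_relation(self.relation.relation_type):
            raise ValueError(
                f"{self.rst_relation!r} is not the image of "
                f"{self.relation.relation_type.value!r}"
            )


Sentence = Union[Message, RhetoricalLink]


@dataclass
class Paragraph:
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class DocumentPlan:
    """Ordered paragraphs of messages and rhetorical links."""

    paragraphs: list[Paragraph] = field(default_factory=list)

    def messages(self) -> Iterator[Message]:
        for paragraph in self.paragraphs:
            for sentence in paragraph.sentences:
                if isinstance(sentence, Message):
                    yield sentence
                else:
                    yield sentence.nucleus
                    yield sentence.satellite

    def event_ids(self) -> set[str]:
        ids: set[str] = set()
        for message in self.messages():
            ids.update(message.event_ids)
        return ids

    def introductions(self) -> dict[str, tuple[int, int]]:
        """First mention of each event, as (paragraph, sentence) coordinates."""
        intro: dict[str, tuple[int, int]] = {}
        for p, paragraph in enumerate(self.paragraphs):
            for s, sentence in enumerate(paragraph.sentences):
                messages = (
                    [sentence]
                    if isinstance(sentence, Message)
                    else [sentence.nucleus, sentence.satellite]
                )
                for message in messages:
                    for event_id in message.event_ids:
                        intro.setdefault(event_id, (p, s))
        return intro


def aggregate(messages: list[Message]) -> list[Message]:
    """Merge maximal runs of ≥2 same-kind mentions into aggregated mentions.

    Two single mentions merge only when their (event class, subtype) are
    equal and no different message intervenes; there is no aggregation
    through generalisation — distinct subtypes never collapse into a
    superordinate mention.  Relative order and the multiset of dates are
    preserved.
    """
    result: list[Message] = []
    run: list[Message] = []

    def flush() -> None:
        if not run:
            return
        if len(run) > 1:
            events = tuple(e for m in run for e in m.events)
            result.append(Message(kind="aggregated_mention", events=events))
        else:
            result.append(run[0])
        run.clear()

    for message in messages:
        if (
            run
            and message.kind == "event_mention"
            and run[-1].kind == "event_mention"
            and message.events[0].event_class is run[-1].events[0].event_class
            and message.events[0].subtype == run[-1].events[0].subtype
        ):
            run.append(message)
            continue
        flush()
        if message.kind == "event_mention":
            run.append(message)
        else:
            result.append(message)
    flush()
    return result


def _relation_between(
    relations: list[Relation], a: set[str], b: set[str]
) -> Optional[Relation]:
    """Deterministically pick a relation joining the two id sets.

    Clinical edges (inference, cause) are preferred over the weaker
    elaboration/follows links; remaining ties break on the relation key.
    """
    priority = {
        RelationType.INFERENCE: 0,
        RelationType.CAUSE: 1,
        RelationType.ELABORATION: 2,
        RelationType.FOLLOWS: 3,
    }
    candidates = [
        rel
        for rel in relations
        if (rel.source in a and rel.target in b)
        or (rel.source in b and rel.target in a)
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda r: (priority[r.relation_type], r.key()))


def _make_link(relation: Relation, by_id: dict[str, Event]) -> RhetoricalLink:
    rst = map_relation(relation.relation_type)
    src = mention(by_id[relation.source])
    tgt = mention(by_id[relation.target])
    if rst == RST_CAUSE:
        # Effect is the nucleus clause, the causing problem the satellite
        # ("... started a chemotherapy course because of the cancer").
        return RhetoricalLink(rst_relation=rst, nucleus=tgt, satellite=src, relation=relation)
    return RhetoricalLink(rst_relation=rst, nucleus=src, satellite=tgt, relation=relation)


def plan_document(content: ContentGraph, chronicle: Chronicle) -> DocumentPlan:
    """Distribute the selected content over paragraphs and sentences.

    One paragraph per (possibly aggregated) spine message.  Within a
    paragraph the spine's own sentence comes first unless the first
    elaboration is directly linked to the spine event, in which case the two
    realise as one sentence through their rhetorical link.  Elaboration
    sentences follow in chronological order of their main-clause event.  A
    spine event with no elaborations but a relation to an already-introduced
    event realises through that link (with a back-reference), so carried
    relations surface in longitudinal reports too.
    """
    by_id = chronicle.events_by_id()
    dates = effective_dates(chronicle)

    spine_messages = aggregate([mention(by_id[event_id]) for event_id in content.spine])

    plan = DocumentPlan()
    introduced: set[str] = set()
    for spine_message in spine_messages:
        spine_ids = set(spine_message.event_ids)
        elab_ids: list[str] = []
        for spine_id in spine_message.event_ids:
            elab_ids.extend(
                entry.event_id for entry in content.elaborations.get(spine_id, [])
            )
        elab_ids = order_event_ids(chronicle, elab_ids, dates)

        units: list[Sentence] = []
        planned_here: set[str] = set()
        for elab_id in elab_ids:
            rel = _relation_between(
                content.included_relations, {elab_id}, spine_ids
            ) or _relation_between(content.included_relations, {elab_id}, planned_here)
            if rel is not None:
                units.append(_make_link(rel, by_id))
            else:
                units.append(mention(by_id[elab_id]))
            planned_here.add(elab_id)

        # An aggregated spine group always states itself first; a single
        # spine event may instead be introduced inside the first link.
        first_unit_covers_spine = (
            spine_message.kind == "event_mention"
            and bool(units)
            and isinstance(units[0], RhetoricalLink)
            and (
                set(units[0].nucleus.event_ids) & spine_ids
                or set(units[0].satellite.event_ids) & spine_ids
            )
        )
        if not first_unit_covers_spine:
            # Spine sentence first; realise through a link back to earlier
            # content when one exists and the spine is a single mention.
            spine_unit: Sentence = spine_message
            if spine_message.kind == "event_mention" and not units:
                rel = _relation_between(
                    content.included_relations, spine_ids, introduced
                )
                if rel is not None:
                    spine_unit = _make_link(rel, by_id)
            units.insert(0, spine_unit)

        paragraph = Paragraph(sentences=units)
        plan.paragraphs.append(paragraph)
        for sentence in units:
            if isinstance(sentence, Message):
                introduced.update(sentence.event_ids)
            else:
                introduced.update(sentence.nucleus.event_ids)
                introduced.update(sentence.satellite.event_ids)
    return plan
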