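"""Content selection: deciding *what* a report will say.

A report is built around a *spine* — the chronologically ordered events
matching the requested focus — which is then elaborated by events reachable
within a bounded number of relation hops (the *depth*).  Depth 0 lists the
focused events alone; depth 1 also pulls in, say, the treatment a diagnosis
caused, but nothing further connected to that treatment.  Longitudinal
reports skip elaboration entirely: every event is principal.

Ordering rule (shared by all selectors): an event's *effective date* is its
own start date, else the date of its nearest dated relation neighbour
(fewest hops; ties broken by the earliest such date); events with no
effective date sort last in their original order.  Dated events sort by
(date, fixed class order, id).  The fixed class order is Diagnosis,
Investigation, Intervention, Prescription, ClinicalProblem.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    Chronicle,
    Event,
    PartialDate,
    Relation,
    ReportKind,
    ReportRequest,
)

__all__ = [
    "ContentGraph",
    "Elaboration",
    "EmptyFocusError",
    "effective_dates",
    "order_event_ids",
    "extract_spine",
    "expand_elaborations",
    "select_longitudinal",
    "select_content",
]


class EmptyFocusError(ValueError):
    """A perspective/user-defined request arrived with no focus classes."""


@dataclass(frozen=True)
class Elaboration:
    """One elaborating event with the relation path back to its spine event."""

    event_id: str
    path: tuple[Relation, ...]


@dataclass
class ContentGraph:
    """What the report will talk about.

    ``spine`` is ordered chronologically; ``elaborations`` maps each spine
    event to the events elaborating it (each attached to exactly one spine
    event — the nearest, with ties going to the earlier spine position);
    ``included_relations`` carries every chronicle relation whose endpoints
    are both selected.
    """

    spine: list[str]
    elaborations: dict[str, list[Elaboration]] = field(default_factory=dict)
    included_relations: list[Relation] = field(default_factory=list)

    def event_ids(self) -> set[str]:
        ids = set(self.spine)
        for entries in self.elaborations.values():
            ids.update(entry.event_id for entry in entries)
        return ids

    def is_empty(self) -> bool:
        return not self.spine


def _adjacency(chronicle: Chronicle) -> dict[str, list[tuple[str, Relation]]]:
    """Undirected adjacency with deterministic neighbour order."""
    adj: dict[str, list[tuple[str, Relation]]] = {e.id: [] for e in chronicle.events}
    for rel in chronicle.relations:
        if rel.source in adj and rel.target in adj:
            adj[rel.source].append((rel.target, rel))
            adj[rel.target].append((rel.source, rel))
    for neighbours in adj.values():
        neighbours.sort(key=lambda pair: (pair[0], pair[1].key()))
    return adj


def effective_dates(chronicle: Chronicle) -> dict[str, Optional[PartialDate]]:
    """Effective date per event: own date, else nearest dated neighbour's.

    Nearest is by undirected relation hops; among equally near dated
    neighbours the earliest date wins.  Events with no dated event in their
    connected component map to ``None``.
    """
    adj = _adjacency(chronicle)
    by_id = chronicle.events_by_id()
    result: dict[str, Optional[PartialDate]] = {}
    for event in chronicle.events:
        if event.start_date is not None:
            result[event.id] = event.start_date
            continue
        best: Optional[PartialDate] = None
        frontier = deque([(event.id, 0)])
        seen = {event.id}
        found_depth: Optional[int] = None
        while frontier:
            node, hops = frontier.popleft()
            if found_depth is not None and hops > found_depth:
                break
            date = by_id[node].start_date
            if date is not None and node != event.id:
                if best is None or date.sort_key() < best.sort_key():
                    best = date
                found_depth = hops
                continue
            for neighbour, _rel in adj[node]:
                if neighbour not in seen:
                    seen.add(neighbour)
                    frontier.append((neighbour, hops + 1))
        result[event.id] = best
    return result


def order_event_ids(
    chronicle: Chronicle,
    ids: list[str],
    dates: Optional[dict[str, Optional[PartialDate]]] = None,
) -> list[str]:
    """Stable chronological order using effective dates.

    Dated events sort by (date, class order, id); undated events keep their
    input order at the end.
    """
    if dates is None:
        dates = effective_dates(chronicle)
    by_id = chronicle.events_by_id()

    def key(event_id: str):
        date = dates.get(event_id)
        if date is None:
            return (1, (0, 0, 0), 0, "")
        return (0, date.sort_key(), by_id[event_id].class_rank, event_id)

    return sorted(ids, key=key)


def _in_period(date: Optional[PartialDate], request: ReportRequest) -> bool:
    if request.period is None:
        return True
    if date is None:
        return False
    key = date.sort_key()
    if key < request.period.start.sort_key():
        return False
    if request.period.end is not None and key > request.period.end.sort_key():
        return False
    return True


def extract_spine(chronicle: Chronicle, request: ReportRequest) -> list[str]:
    """Events matching the focus (and period), in chronological order.

    Class must match a focus entry; when the entry names a subtype, the
    subtype must match too.  Raises :class:`EmptyFocusError` when a
    perspective/user-defined request has no focus classes.
    """
    if not request.focus_classes:
        raise EmptyFocusError(f"{request.kind.value} request needs focus classes")
    dates = effective_dates(chronicle)
    matched = [
        event.id
        for event in chronicle.events
        if any(spec.matches(event) for spec in request.focus_classes)
        and _in_period(dates[event.id], request)
    ]
    return order_event_ids(chronicle, matched, dates)


def expand_elaborations(
    chronicle: Chronicle, spine: list[str], depth: int
) -> ContentGraph:
    """Attach to each spine event the events within ``depth`` relation hops.

    Relations are traversed in both directions (a problem's summary needs
    both the investigation that revealed it and the treatment it caused).
    An event reachable from several spine events is attached only to the
    nearest one; ties go to the earlier spine position.  Spine events are
    never elaborations.  Depth 0 yields no elaborations.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    spine_set = set(spine)
    adj = _adjacency(chronicle)
    dates = effective_dates(chronicle)

    # Per-spine BFS recording distance and first-found path.
    reach: dict[str, list[tuple[int, int, tuple[Relation, ...]]]] = {}
    for position, spine_id in enumerate(spine):
        dist: dict[str, int] = {spine_id: 0}
        paths: dict[str, tuple[Relation, ...]] = {spine_id: ()}
        frontier = deque([spine_id])
        while frontier:
            node = frontier.popleft()
            if dist[node] >= depth:
                continue
            for neighbour, rel in adj[node]:
                if neighbour not in dist:
                    dist[neighbour] = dist[node] + 1
                    paths[neighbour] = paths[node] + (rel,)
                    frontier.append(neighbour)
        for node, d in dist.items():
            if node in spine_set:
                continue
            reach.setdefault(node, []).append((d, position, paths[node]))

    elaborations: dict[str, list[Elaboration]] = {s: [] for s in spine}
    for node, options in reach.items():
        d, position, path = min(options, key=lambda item: (item[0], item[1]))
        elaborations[spine[position]].append(Elaboration(event_id=node, path=path))

    for spine_id, entries in elaborations.items():
        ordered = order_event_ids(chronicle, [e.event_id for e in entries], dates)
        rank = {event_id: i for i, event_id in enumerate(ordered)}
        entries.sort(key=lambda e: rank[e.event_id])

    selected = spine_set | set(reach)
    included = [
        rel
        for rel in chronicle.relations
        if rel.source in selected and rel.target in selected
    ]
    return ContentGraph(
        spine=list(spine), elaborations=elaborations, included_relations=included
    )


def select_longitudinal(chronicle: Chronicle, request: ReportRequest) -> ContentGraph:
    """Everything is principal: all events (in period), fully ordered.

    Chronological order with same-date blocks grouped by the fixed class
    order; undated events take the date of their nearest dated relation
    neighbour, and events with no effective date go last (excluded when a
    period filter is set, since membership cannot be established).
    """
    dates = effective_dates(chronicle)
    ids = [e.id for e in chronicle.events if _in_period(dates[e.id], request)]
    spine = order_event_ids(chronicle, ids, dates)
    selected = set(spine)
    included = [
        rel
        for rel in chronicle.relations
        if rel.source in selected and rel.target in selected
    ]
    return ContentGraph(
        spine=spine,
        elaborations={s: [] for s in spine},
        included_relations=included,
    )


def select_content(chronicle: Chronicle, request: ReportRequest) -> ContentGraph:
    """Dispatch on report kind; the single entry point used by the pipeline."""
    if request.kind is ReportKind.LONGITUDINAL:
        return select_longitudinal(chronicle, request)
    spine = extract_spine(chronicle, request)
    return expand_elaborations(chronicle, spine, request.depth)
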