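"""Independent brute-force oracles for the selection and planning rules.

These deliberately avoid the package's own traversal code: graph reachability
goes through networkx shortest-path queries instead of the hand-rolled BFS,
and ordering/grouping is recomputed from the documented rules from scratch.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx

from chronica.model import (
    Chronicle,
    PartialDate,
    RelationType,
    ReportRequest,
)


def relation_graph(chronicle: Chronicle) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(e.id for e in chronicle.events)
    for rel in chronicle.relations:
        g.add_edge(rel.source, rel.target)
    return g


def oracle_effective_dates(chronicle: Chronicle) -> dict[str, Optional[PartialDate]]:
    """Own date, else nearest dated neighbour (fewest hops, earliest date)."""
    g = relation_graph(chronicle)
    by_id = chronicle.events_by_id()
    out: dict[str, Optional[PartialDate]] = {}
    for event in chronicle.events:
        if event.start_date is not None:
            out[event.id] = event.start_date
            continue
        lengths = nx.single_source_shortest_path_length(g, event.id)
        dated = [
            (hops, by_id[other].start_date)
            for other, hops in lengths.items()
            if other != event.id and by_id[other].start_date is not None
        ]
        if not dated:
            out[event.id] = None
            continue
        best_hops = min(h for h, _ in dated)
        candidates = [d for h, d in dated if h == best_hops]
        out[event.id] = min(candidates, key=lambda d: d.sort_key())
    return out


def oracle_order(chronicle: Chronicle, ids: list[str]) -> list[str]:
    """(date, class order, id) for dated events; undated last in input order."""
    dates = oracle_effective_dates(chronicle)
    by_id = chronicle.events_by_id()
    dated = [i for i in ids if dates[i] is not None]
    undated = [i for i in ids if dates[i] is None]
    dated.sort(key=lambda i: (dates[i].sort_key(), by_id[i].class_rank, i))
    return dated + undated


def oracle_spine(chronicle: Chronicle, request: ReportRequest) -> list[str]:
    """Linear filter on focus and period, then the documented sort."""
    dates = oracle_effective_dates(chronicle)
    kept = []
    for event in chronicle.events:
        if not any(spec.matches(event) for spec in request.focus_classes):
            continue
        if request.period is not None:
            date = dates[event.id]
            if date is None:
                continue
            if date.sort_key() < request.period.start.sort_key():
                continue
            if (
                request.period.end is not None
                and date.sort_key() > request.period.end.sort_key()
            ):
                continue
        kept.append(event.id)
    return oracle_order(chronicle, kept)


def oracle_elaborations(
    chronicle: Chronicle, spine: list[str], depth: int
) -> dict[str, set[str]]:
    """Attachment map via all-pairs shortest paths: nearest spine event wins,
    ties broken by earlier spine position; spine events never elaborate."""
    g = relation_graph(chronicle)
    spine_set = set(spine)
    attach: dict[str, set[str]] = {s: set() for s in spine}
    distances = {s: nx.single_source_shortest_path_length(g, s, cutoff=depth)
                 for s in spine}
    for event in chronicle.events:
        if event.id in spine_set:
            continue
        options = [
            (dist[event.id], position)
            for position, (spine_id, dist) in enumerate(
                (s, distances[s]) for s in spine
            )
            if event.id in dist
        ]
        if options:
            _, position = min(options)
            attach[spine[position]].add(event.id)
    return attach


def oracle_aggregate_runs(keys: list[tuple]) -> list[list[int]]:
    """Run-length grouping of equal consecutive keys; returns index groups."""
    groups: list[list[int]] = []
    for index, key in enumerate(keys):
        if groups and keys[groups[-1][-1]] == key:
            groups[-1].append(index)
        else:
            groups.append([index])
    return groups


def dfs_has_cycle(nodes: set[str], edges: list[tuple[str, str]]) -> bool:
    """Depth-first search cycle detection over a directed edge list."""
    adjacency: dict[str, list[str]] = {n: [] for n in nodes}
    for src, tgt in edges:
        adjacency[src].append(tgt)
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {n: WHITE for n in nodes}

    def visit(node: str) -> bool:
        colour[node] = GREY
        for nxt in adjacency[node]:
            if colour[nxt] == GREY:
                return True
            if colour[nxt] == WHITE and visit(nxt):
                return True
        colour[node] = BLACK
        return False

    return any(colour[n] == WHITE and visit(n) for n in nodes)
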