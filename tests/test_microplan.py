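"""Microplanning: relation mapping, conceptual aggregation, paragraph plans."""

from __future__ import annotations

import random

import pytest

from chronica.microplan import (
    RST_CAUSE,
    RST_ELABORATION,
    RST_RESULT,
    RST_SEQUENCE,
    Message,
    RhetoricalLink,
    aggregate,
    map_relation,
    mention,
    plan_document,
)
from chronica.model import (
    DateSpan,
    Event,
    EventClass,
    FocusSpec,
    PartialDate,
    RelationType,
    ReportKind,
    ReportRequest,
)
from chronica.selection import select_content

from .conftest import make_random_chronicle
from .oracles import oracle_aggregate_runs


def _dated_event(event_id, event_class, subtype, month, day):
    return Event(
        id=event_id,
        event_class=event_class,
        subtype=subtype,
        time=DateSpan(start=PartialDate(year=2001, month=month, day=day)),
    )


class TestMapRelation:
    @pytest.mark.parametrize(
        "domain, rst",
        [
            (RelationType.INFERENCE, RST_RESULT),
            (RelationType.CAUSE, RST_CAUSE),
            (RelationType.ELABORATION, RST_ELABORATION),
            (RelationType.FOLLOWS, RST_SEQUENCE),
        ],
    )
    def test_fixed_total_mapping(self, domain, rst):
        assert map_relation(domain) == rst

    def test_unknown_relation_type_raises(self):
        with pytest.raises(ValueError):
            map_relation("correlates")


# Expected grouping computed with the independent run-length oracle: three
# consecutive equal (class, subtype) keys form one group of three.
_TRANSFUSION_KEY = (EventClass.INTERVENTION, "blood transfusion")
assert oracle_aggregate_runs([_TRANSFUSION_KEY] * 3) == [[0, 1, 2]]


class TestAggregate:
    def test_three_transfusions_merge_with_all_dates(self):
        messages = [
            mention(_dated_event(f"t{i}", EventClass.INTERVENTION, "blood transfusion", 3 + i, 1))
            for i in range(3)
        ]
        merged = aggregate(messages)
        assert len(merged) == 1
        assert merged[0].kind == "aggregated_mention"
        assert len(merged[0].dates) == 3
        assert [d.month for d in merged[0].dates] == [3, 4, 5]

    def test_no_generalisation_across_subtypes(self):
        messages = [
            mention(_dated_event("c", EventClass.INTERVENTION, "chemotherapy course", 3, 1)),
            mention(_dated_event("r", EventClass.INTERVENTION, "radiotherapy course", 4, 1)),
        ]
        assert aggregate(messages) == messages

    def test_empty_list(self):
        assert aggregate([]) == []

    def test_intervening_message_blocks_merge(self):
        messages = [
            mention(_dated_event("t1", EventClass.INTERVENTION, "blood transfusion", 3, 1)),
            mention(_dated_event("x", EventClass.INVESTIGATION, "biopsy", 3, 2)),
            mention(_dated_event("t2", EventClass.INTERVENTION, "blood transfusion", 3, 3)),
        ]
        merged = aggregate(messages)
        assert [m.kind for m in merged] == ["event_mention"] * 3

    def test_matches_run_length_oracle_on_random_lists(self):
        rng = random.Random(2024)
        subtypes = ["biopsy", "CT scan", "blood transfusion"]
        for _ in range(300):
            events = [
                _dated_event(
                    f"e{i}",
                    rng.choice([EventClass.INTERVENTION, EventClass.INVESTIGATION]),
                    rng.choice(subtypes),
                    rng.randint(1, 12),
                    rng.randint(1, 28),
                )
                for i in range(rng.randint(0, 12))
            ]
            messages = [mention(e) for e in events]
            merged = aggregate(messages)
            keys = [(e.event_class, e.subtype) for e in events]
            groups = oracle_aggregate_runs(keys)
            expected_sizes = [len(g) for g in groups]
            assert [len(m.events) for m in merged] == expected_sizes
            # order and date multiset preserved
            flat = [e.id for m in merged for e in m.events]
            assert flat == [e.id for e in events]

    def test_aggregated_message_invariants(self):
        with pytest.raises(ValueError):
            Message(kind="aggregated_mention", events=(
                _dated_event("a", EventClass.INTERVENTION, "surgery", 1, 1),
            ))
        with pytest.raises(ValueError):
            Message(kind="aggregated_mention", events=(
                _dated_event("a", EventClass.INTERVENTION, "surgery", 1, 1),
                _dated_event("b", EventClass.INTERVENTION, "biopsy", 2, 1),
            ))


class TestPlanDocument:
    def test_worked_example_plan_shape(self, worked, problems_request):
        content = select_content(worked, problems_request)
        plan = plan_document(content, worked)
        assert len(plan.paragraphs) == 1
        sentences = plan.paragraphs[0].sentences
        assert len(sentences) == 2
        first, second = sentences
        assert isinstance(first, RhetoricalLink) and first.rst_relation == RST_RESULT
        assert first.nucleus.event_ids == ("biopsy",)
        assert first.satellite.event_ids == ("cancer",)
        assert isinstance(second, RhetoricalLink) and second.rst_relation == RST_CAUSE
        assert second.nucleus.event_ids == ("chemo1",)

    def test_empty_content_empty_plan(self, worked):
        request = ReportRequest(
            kind=ReportKind.PERSPECTIVE,
            focus_classes=[FocusSpec(event_class=EventClass.PRESCRIPTION)],
        )
        content = select_content(worked, request)
        plan = plan_document(content, worked)
        assert plan.paragraphs == []

    def test_paragraph_count_equals_aggregated_group_count(self, corpus):
        request = ReportRequest(kind=ReportKind.LONGITUDINAL)
        for chronicle in corpus[:40]:
            content = select_content(chronicle, request)
            plan = plan_document(content, chronicle)
            by_id = chronicle.events_by_id()
            keys = [
                (by_id[i].event_class, by_id[i].subtype) for i in content.spine
            ]
            assert len(plan.paragraphs) == len(oracle_aggregate_runs(keys))

    def test_content_fidelity_on_corpus(self, corpus):
        request = ReportRequest(kind=ReportKind.LONGITUDINAL)
        for chronicle in corpus:
            content = select_content(chronicle, request)
            plan = plan_document(content, chronicle)
            assert plan.event_ids() == content.event_ids()
            # each event introduced exactly once, and introductions cover all
            assert set(plan.introductions()) == content.event_ids()

    def test_aggregation_preserves_dates_in_plan(self, corpus):
        request = ReportRequest(kind=ReportKind.LONGITUDINAL)
        for chronicle in corpus[:40]:
            content = select_content(chronicle, request)
            plan = plan_document(content, chronicle)
            by_id = chronicle.events_by_id()
            planned_dates = sorted(
                d.sort_key()
                for intro_id in plan.introductions()
                if (d := by_id[intro_id].start_date) is not None
            )
            spine_dates = sorted(
                d.sort_key()
                for i in content.spine
                if (d := by_id[i].start_date) is not None
            )
            assert planned_dates == spine_dates
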