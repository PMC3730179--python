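"""Surface realisation: date phrases, clause templates, golden paragraph."""

from __future__ import annotations

import pytest

from chronica.microplan import RhetoricalLink, mention, plan_document
from chronica.model import (
    DateSpan,
    Event,
    EventClass,
    FocusSpec,
    PartialDate,
    Relation,
    RelationType,
    ReportKind,
    ReportRequest,
)
from chronica.pipeline import generate_report
from chronica.realise import (
    Lexicon,
    LexiconError,
    Realiser,
    format_date,
    indefinite_article,
    load_default_lexicon,
    pluralise,
    realise_document,
    realise_link,
    realise_message,
)
from chronica.selection import select_content
from chronica.synthetic import worked_example_chronicle

from .conftest import GOLDEN_PARAGRAPH


class TestFormatDate:
    @pytest.mark.parametrize(
        "date, expected",
        [
            (PartialDate(month=10, day=15), "On 15th October"),
            (PartialDate(month=12, day=1), "On 1st December"),
            (PartialDate(year=2001, month=3, day=12), "On 12th March 2001"),
            (PartialDate(year=2001, month=3, day=11), "On 11th March 2001"),
            (PartialDate(year=2001, month=3, day=13), "On 13th March 2001"),
            (PartialDate(year=2001, month=3, day=22), "On 22nd March 2001"),
            (PartialDate(year=2001, month=3, day=23), "On 23rd March 2001"),
            (PartialDate(year=2001, month=10), "In October 2001"),
            (PartialDate(month=10), "In October"),
        ],
    )
    def test_date_phrases(self, date, expected):
        assert format_date(date) == expected

    def test_bare_form_drops_preposition(self):
        assert format_date(PartialDate(month=10, day=15), fronted=False) == "15th October"


def test_indefinite_article_handles_initialisms():
    assert indefinite_article("biopsy") == "a"
    assert indefinite_article("ultrasound") == "an"
    assert indefinite_article("MRI scan") == "an"
    assert indefinite_article("X-ray") == "an"
    assert indefinite_article("CT scan") == "a"


def test_pluralise_basic_forms():
    assert pluralise("blood transfusion") == "blood transfusions"
    assert pluralise("biopsy") == "biopsies"
    assert pluralise("chemotherapy course") == "chemotherapy courses"


class TestRealiseMessage:
    def test_biopsy_clause(self, worked):
        text = realise_message(mention(worked.get_event("biopsy")))
        assert text == "On 15th October, the patient had a biopsy of the left breast"

    def test_chemo_clause(self, worked):
        text = realise_message(mention(worked.get_event("chemo1")))
        assert text == "On 1st December, the patient started a chemotherapy course (CC1)"

    def test_undated_event_drops_date_phrase(self):
        event = Event(
            id="b2",
            event_class=EventClass.INVESTIGATION,
            subtype="biopsy",
            attributes={"locus": "left breast"},
        )
        assert realise_message(mention(event)) == "the patient had a biopsy of the left breast"

    def test_aggregated_mention_counts_and_conjoins_dates(self):
        events = tuple(
            Event(
                id=f"t{i}",
                event_class=EventClass.INTERVENTION,
                subtype="blood transfusion",
                time=DateSpan(start=PartialDate(month=3 + i, day=i + 1)),
            )
            for i in range(3)
        )
        from chronica.microplan import Message

        text = realise_message(Message(kind="aggregated_mention", events=events))
        assert text == (
            "the patient had 3 blood transfusions "
            "(on 1st March, 2nd April, and 3rd May)"
        )

    def test_missing_lexicon_entry_names_key(self, worked):
        empty = Lexicon(classes={})
        with pytest.raises(LexiconError) as exc:
            realise_message(mention(worked.get_event("biopsy")), lexicon=empty)
        assert exc.value.key == ("Investigation", "biopsy")


class TestRealiseLink:
    def test_result_link(self, worked):
        link = RhetoricalLink(
            rst_relation="result",
            nucleus=mention(worked.get_event("biopsy")),
            satellite=mention(worked.get_event("cancer")),
            relation=worked.relations[0],
        )
        assert realise_link(link) == (
            "On 15th October, the patient had a biopsy of the left breast "
            "which revealed cancer."
        )

    def test_cause_link(self, worked):
        link = RhetoricalLink(
            rst_relation="cause",
            nucleus=mention(worked.get_event("chemo1")),
            satellite=mention(worked.get_event("cancer")),
            relation=worked.relations[1],
        )
        # fresh registry: the cancer is a first mention here, hence bare and
        # fully described (the chemo shares no locus to make it redundant)
        assert realise_link(link) == (
            "On 1st December, the patient started a chemotherapy course (CC1) "
            "because of cancer of the left breast."
        )

    def test_rst_relation_must_match_domain_relation(self, worked):
        with pytest.raises(ValueError):
            RhetoricalLink(
                rst_relation="cause",
                nucleus=mention(worked.get_event("biopsy")),
                satellite=mention(worked.get_event("cancer")),
                relation=worked.relations[0],  # an inference edge
            )

    def test_sequence_link(self):
        a = Event(
            id="a", event_class=EventClass.INVESTIGATION, subtype="CT scan",
            time=DateSpan(start=PartialDate(year=2001, month=5, day=2)),
        )
        b = Event(
            id="b", event_class=EventClass.INTERVENTION, subtype="surgery",
            time=DateSpan(start=PartialDate(year=2001, month=6, day=3)),
        )
        link = RhetoricalLink(
            rst_relation="sequence",
            nucleus=mention(a),
            satellite=mention(b),
            relation=Relation(source="a", target="b", relation_type=RelationType.FOLLOWS),
        )
        text = realise_link(link)
        assert text == (
            "On 2nd May 2001, the patient had a CT scan and subsequently "
            "the patient underwent surgery."
        )


class TestRealiseDocument:
    def test_golden_worked_example(self, worked, problems_request):
        report = generate_report(worked, problems_request)
        assert report.text == GOLDEN_PARAGRAPH

    def test_empty_plan_empty_body(self, worked):
        request = ReportRequest(
            kind=ReportKind.PERSPECTIVE,
            focus_classes=[FocusSpec(event_class=EventClass.PRESCRIPTION)],
        )
        assert generate_report(worked, request).text == ""

    def test_deterministic(self, corpus):
        request = ReportRequest(kind=ReportKind.LONGITUDINAL)
        for chronicle in corpus[:10]:
            assert (
                generate_report(chronicle, request).text
                == generate_report(chronicle, request).text
            )

    def test_sentence_count_matches_plan(self, corpus):
        request = ReportRequest(kind=ReportKind.LONGITUDINAL)
        for chronicle in corpus[:30]:
            content = select_content(chronicle, request)
            plan = plan_document(content, chronicle)
            text = realise_document(plan)
            n_planned = sum(len(p.sentences) for p in plan.paragraphs)
            n_realised = text.count(".") if text else 0
            assert n_realised == n_planned

    def test_no_hallucinated_mentions(self, corpus):
        request = ReportRequest(kind=ReportKind.LONGITUDINAL)
        for chronicle in corpus[:40]:
            report = generate_report(chronicle, request)
            assert report.realisation.mentioned_ids() == report.content.event_ids()

    def test_first_mention_indefinite_then_definite(self, worked, problems_request):
        report = generate_report(worked, problems_request)
        assert "revealed cancer" in report.text  # bare first mention
        assert "because of the cancer" in report.text  # definite back-reference


class TestLexiconRobustness:
    def test_unseen_subtype_of_known_class_realises(self):
        """A brand-new word of a known type needs no rule edits."""
        event = Event(
            id="m1",
            event_class=EventClass.INTERVENTION,
            subtype="mastectomy",
            time=DateSpan(start=PartialDate(month=11, day=2)),
        )
        text = realise_message(mention(event))
        assert text == "On 2nd November, the patient underwent a mastectomy"

    def test_subtype_override_beats_class_default(self):
        lexicon = load_default_lexicon()
        entry = lexicon.resolve("Intervention", "chemotherapy course")
        assert entry.verb == "started"
        assert lexicon.resolve("Intervention", "appendectomy").verb == "underwent"

    def test_runtime_subtype_addition(self):
        lexicon = load_default_lexicon()
        lexicon.add_subtype("Investigation", "lumbar puncture", verb="received")
        event = Event(
            id="lp", event_class=EventClass.INVESTIGATION, subtype="lumbar puncture"
        )
        assert realise_message(mention(event), lexicon=lexicon) == (
            "the patient received a lumbar puncture"
        )
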