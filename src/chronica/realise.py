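"""Surface realisation: turning a document plan into English text.

Two rule families drive the realiser, mirroring the split between what is
generic about English and what is specific to the clinical domain:

* a small *grammar* of phrase and sentence patterns (definite noun phrase,
  causal sentence, ...), shipped as data in ``data/grammar.yaml`` and never
  touched by new vocabulary;
* a *lexicon* of clause templates keyed by event class with subtype
  overrides (``data/lexicon.yaml``).  Because lookup falls back to the
  class entry, an unseen subtype of a known class — a "mastectomy"
  intervention, say — realises correctly with no rule edits.

Referring expressions follow a per-document mention registry: the first
mention of an event is full ("a biopsy of the left breast", bare "cancer"),
later mentions are definite back-references ("the cancer").  The registry
also yields a mention trace, so tests can confirm that every noun phrase in
the output maps back to a planned message — no hallucinated content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .microplan import (
    RST_CAUSE,
    RST_ELABORATION,
    RST_RESULT,
    RST_SEQUENCE,
    DocumentPlan,
    Message,
    RhetoricalLink,
)
from .model import Event, PartialDate

__all__ = [
    "LexiconError",
    "LexiconEntry",
    "Lexicon",
    "Grammar",
    "Mention",
    "RealisedReport",
    "Realiser",
    "load_default_lexicon",
    "load_default_grammar",
    "format_date",
    "realise_message",
    "realise_link",
    "realise_document",
]

_MONTHS = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)


class LexiconError(KeyError):
    """No lexicon entry resolves the requested (event class, subtype) key."""

    def __init__(self, event_class: str, subtype: str) -> None:
        super().__init__(f"no lexicon entry for ({event_class}, {subtype})")
        self.key = (event_class, subtype)


@dataclass(frozen=True)
class LexiconEntry:
    """Clause template: verb group, article policy, optional noun forms."""

    verb: str = "had"
    article: str = "auto"  # "auto" → indefinite a/an; "none" → bare NP
    noun: Optional[str] = None
    plural: Optional[str] = None


class Lexicon:
    """Class-level defaults with subtype overrides.

    ``resolve`` merges the subtype entry (if any) over the class entry;
    a class with no entry at all raises :class:`LexiconError`, naming the
    unresolved key.
    """

    def __init__(
        self,
        classes: dict[str, LexiconEntry],
        subtypes: Optional[dict[str, dict[str, dict]]] = None,
    ) -> None:
        self.classes = dict(classes)
        self.subtypes = {k: dict(v) for k, v in (subtypes or {}).items()}

    @classmethod
    def from_dict(cls, data: dict) -> "Lexicon":
        classes = {
            name: LexiconEntry(**(entry or {}))
            for name, entry in (data.get("classes") or {}).items()
        }
        subtypes = {
            cls_name: {sub: dict(entry or {}) for sub, entry in table.items()}
            for cls_name, table in (data.get("subtypes") or {}).items()
        }
        return cls(classes, subtypes)

    def add_subtype(self, event_class: str, subtype: str, **fields) -> None:
        self.subtypes.setdefault(event_class, {})[subtype] = fields

    def resolve(self, event_class: str, subtype: str) -> LexiconEntry:
        if event_class not in self.classes:
            raise LexiconError(event_class, subtype)
        base = self.classes[event_class]
        override = self.subtypes.get(event_class, {}).get(subtype)
        if not override:
            return base
        merged = {
            "verb": base.verb,
            "article": base.article,
            "noun": base.noun,
            "plural": base.plural,
        }
        merged.update(override)
        return LexiconEntry(**merged)


class Grammar:
    """Phrase/sentence expansion rules plus discourse connectives."""

    REQUIRED_RULES = ("definite_noun_phrase", "causal_sentence")

    def __init__(self, rules: dict[str, list[str]], connectives: dict[str, str],
                 articles: Optional[dict[str, str]] = None) -> None:
        for name in self.REQUIRED_RULES:
            if name not in rules:
                raise ValueError(f"grammar is missing required rule {name!r}")
        self.rules = rules
        self.connectives = connectives
        self.articles = articles or {"definite": "the"}

    @classmethod
    def from_dict(cls, data: dict) -> "Grammar":
        return cls(
            rules=dict(data.get("rules") or {}),
            connectives=dict(data.get("connectives") or {}),
            articles=dict(data.get("articles") or {}),
        )

    def expand(self, rule: str, slots: dict[str, str]) -> str:
        """Fill a rule's constituents and join the non-empty ones."""
        parts = [slots.get(name, "") for name in self.rules[rule]]
        return " ".join(part for part in parts if part)


def _load_yaml(name: str) -> dict:
    text = resources.files("chronica.data").joinpath(name).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def load_default_lexicon() -> Lexicon:
    return Lexicon.from_dict(_load_yaml("lexicon.yaml"))


def load_default_grammar() -> Grammar:
    return Grammar.from_dict(_load_yaml("grammar.yaml"))


def _ordinal(day: int) -> str:
    if 11 <= day % 100 <= 13:
        suffix = "th"
    else:
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(day % 10, "th")
    return f"{day}{suffix}"


def format_date(date: PartialDate, fronted: bool = True) -> str:
    """Render a date phrase: "On 15th October", "In March 2001".

    Day precision uses an ordinal day; month precision drops the day.  The
    year appears only when the date carries one.  ``fronted=False`` yields
    the bare phrase without the preposition ("15th October").
    """
    month = _MONTHS[date.month - 1]
    if date.precision == "day":
        core = f"{_ordinal(date.day)} {month}"
        preposition = "On"
    else:
        core = month
        preposition = "In"
    if date.year is not None:
        core += f" {date.year}"
    return f"{preposition} {core}" if fronted else core


_INITIALISM_AN = set("AEFHILMNORSX")


def indefinite_article(noun: str) -> str:
    """Choose a/an, treating all-caps initialisms by letter name (an MRI)."""
    word = noun.split()[0]
    head = word.split("-")[0]
    if head.isupper() and head:  # "MRI", "X" in "X-ray"
        return "an" if head[0] in _INITIALISM_AN else "a"
    return "an" if word[0].lower() in "aeiou" else "a"


def pluralise(noun: str) -> str:
    head = noun.split()[-1]
    rest = noun[: len(noun) - len(head)]
    if head.endswith("y") and head[-2:-1].lower() not in "aeiou":
        head = head[:-1] + "ies"
    elif head.endswith(("s", "x", "z", "ch", "sh")):
        head += "es"
    else:
        head += "s"
    return rest + head


@dataclass(frozen=True)
class Mention:
    """One realised reference to an event, with sentence coordinates."""

    event_id: str
    paragraph: int
    sentence: int
    kind: str  # "introduction" | "reference"


@dataclass
class RealisedReport:
    text: str
    mentions: list[Mention] = field(default_factory=list)

    def mentioned_ids(self) -> set[str]:
        return {m.event_id for m in self.mentions}


class Realiser:
    """Stateful document realiser (mention registry lives per document)."""

    def __init__(self, lexicon: Optional[Lexicon] = None,
                 grammar: Optional[Grammar] = None) -> None:
        self.lexicon = lexicon if lexicon is not None else load_default_lexicon()
        self.grammar = grammar if grammar is not None else load_default_grammar()
        self._introduced: set[str] = set()
        self._mentions: list[Mention] = []
        self._coords = (0, 0)

    # -- noun phrases -----------------------------------------------------

    def _record(self, event: Event, kind: str) -> None:
        p, s = self._coords
        self._mentions.append(
            Mention(event_id=event.id, paragraph=p, sentence=s, kind=kind)
        )

    def _noun(self, event: Event) -> str:
        entry = self.lexicon.resolve(event.event_class.value, event.subtype)
        return entry.noun or event.subtype

    def noun_phrase(self, event: Event, omit_post_modifier: bool = False) -> str:
        """Full NP at first mention, definite back-reference afterwards.

        ``omit_post_modifier`` suppresses the locus/content modifier when
        the surrounding sentence has already expressed it (a biopsy of the
        left breast reveals "cancer", not "cancer of the left breast").
        """
        if event.id in self._introduced:
            self._record(event, "reference")
            return self.grammar.expand(
                "definite_noun_phrase",
                {"definite_article": self.grammar.articles["definite"],
                 "noun": self._noun(event)},
            )
        entry = self.lexicon.resolve(event.event_class.value, event.subtype)
        noun = entry.noun or event.subtype
        slots = {
            "noun": noun,
            "post_modifier": "" if omit_post_modifier else self._post_modifier(event),
            "parenthetical": self._parenthetical(event),
        }
        if entry.article == "none":
            phrase = self.grammar.expand("bare_noun_phrase", slots)
        else:
            slots["indefinite_article"] = indefinite_article(noun)
            phrase = self.grammar.expand("indefinite_noun_phrase", slots)
        self._introduced.add(event.id)
        self._record(event, "introduction")
        return phrase

    @staticmethod
    def _post_modifier(event: Event) -> str:
        locus = event.attributes.get("locus")
        if locus:
            return f"of the {locus}"
        content = event.attributes.get("content")
        if content:
            return f"of {content}"
        return ""

    @staticmethod
    def _parenthetical(event: Event) -> str:
        label = event.attributes.get("label")
        if label:
            return f"({label})"
        stage = event.attributes.get("stage")
        if stage:
            return f"(stage {stage})"
        return ""

    # -- clauses ----------------------------------------------------------

    def clause(self, event: Event, with_date: bool = True) -> str:
        """"On 15th October, the patient had a biopsy of the left breast"."""
        entry = self.lexicon.resolve(event.event_class.value, event.subtype)
        body = self.grammar.expand(
            "clause",
            {"subject": "the patient", "verb": entry.verb,
             "object": self.noun_phrase(event)},
        )
        date_phrase = ""
        if with_date and event.time is not None:
            start = event.time.start
            if event.time.end is not None and event.time.end != start:
                date_phrase = (
                    f"From {format_date(start, fronted=False)} "
                    f"to {format_date(event.time.end, fronted=False)},"
                )
            else:
                date_phrase = format_date(start) + ","
        return self.grammar.expand(
            "dated_clause", {"date_phrase": date_phrase, "clause": body}
        )

    def aggregated_clause(self, message: Message) -> str:
        """"the patient had 3 blood transfusions (on ..., ..., and ...)"."""
        events = message.events
        sample = events[0]
        entry = self.lexicon.resolve(sample.event_class.value, sample.subtype)
        noun = entry.noun or sample.subtype
        plural = entry.plural or pluralise(noun)
        obj = f"{len(events)} {plural}"
        loci = {e.attributes.get("locus") for e in events}
        if len(loci) == 1 and next(iter(loci)):
            obj += f" of the {next(iter(loci))}"
        dates = [format_date(d, fronted=False) for d in message.dates]
        if dates:
            if len(dates) == 1:
                listed = dates[0]
            else:
                listed = ", ".join(dates[:-1]) + f", and {dates[-1]}"
            obj += f" (on {listed})"
        for event in events:
            self._introduced.add(event.id)
            self._record(event, "introduction")
        return self.grammar.expand(
            "clause",
            {"subject": "the patient", "verb": entry.verb, "object": obj},
        )

    # -- sentences --------------------------------------------------------

    def message_text(self, message: Message) -> str:
        if message.kind == "aggregated_mention":
            return self.aggregated_clause(message)
        return self.clause(message.events[0])

    def link_text(self, link: RhetoricalLink) -> str:
        nucleus = link.nucleus.events[0]
        satellite = link.satellite.events[0]
        if link.rst_relation == RST_RESULT:
            return self._result_text(nucleus, satellite)
        if link.rst_relation == RST_CAUSE:
            return self._cause_text(nucleus, satellite)
        if link.rst_relation == RST_SEQUENCE:
            return self._sequence_text(nucleus, satellite)
        if link.rst_relation == RST_ELABORATION:
            return self._elaboration_text(nucleus, satellite)
        raise ValueError(f"unknown rhetorical relation {link.rst_relation!r}")

    @staticmethod
    def _same_locus(a: Event, b: Event) -> bool:
        locus = a.attributes.get("locus")
        return bool(locus) and locus == b.attributes.get("locus")

    def _result_text(self, nucleus: Event, satellite: Event) -> str:
        """"... had a biopsy which revealed cancer"; the nucleus is the
        revealing investigation.  With the nucleus already introduced, the
        revelation is stated directly: "The biopsy revealed cancer"."""
        omit = self._same_locus(nucleus, satellite)
        if nucleus.id in self._introduced:
            self._record(nucleus, "reference")
            subject = self.grammar.expand(
                "definite_noun_phrase",
                {"definite_article": self.grammar.articles["definite"],
                 "noun": self._noun(nucleus)},
            )
            return f"{subject} revealed {self.noun_phrase(satellite, omit_post_modifier=omit)}"
        return self.grammar.expand(
            "result_sentence",
            {
                "main_clause": self.clause(nucleus),
                "relative_connector": self.grammar.connectives["result"],
                "object": self.noun_phrase(satellite, omit_post_modifier=omit),
            },
        )

    def _cause_text(self, nucleus: Event, satellite: Event) -> str:
        """Nucleus is the effect clause, satellite the causing problem:
        "... started a chemotherapy course (CC1) because of the cancer"."""
        if nucleus.id in self._introduced:
            self._record(nucleus, "reference")
            main = self.grammar.expand(
                "definite_noun_phrase",
                {"definite_article": self.grammar.articles["definite"],
                 "noun": self._noun(nucleus)},
            ) + " was"
        else:
            main = self.clause(nucleus)
        return self.grammar.expand(
            "causal_sentence",
            {
                "main_clause": main,
                "causal_connector": self.grammar.connectives["cause"],
                "subordinate_phrase": self.noun_phrase(
                    satellite, omit_post_modifier=self._same_locus(nucleus, satellite)
                ),
            },
        )

    @staticmethod
    def _embed(clause: str) -> str:
        """Lower-case a clause for mid-sentence embedding ("on 3rd May, ...")."""
        return clause[0].lower() + clause[1:] if clause else clause

    def _sequence_text(self, nucleus: Event, satellite: Event) -> str:
        new_first = nucleus.id not in self._introduced
        new_second = satellite.id not in self._introduced
        if new_first and new_second:
            first = self.clause(nucleus)
            second = self.clause(satellite, with_date=False)
            return f"{first} and subsequently {second}"
        subject = satellite if new_second or not new_first else nucleus
        return self.grammar.expand(
            "sequence_sentence",
            {
                "temporal_connective": self.grammar.connectives["sequence"],
                "main_clause": self._embed(self.clause(subject)),
            },
        )

    def _elaboration_text(self, nucleus: Event, satellite: Event) -> str:
        # Elaborations stand as their own sentence; realise whichever side
        # is new (the satellite by convention, both when neither has been
        # introduced yet).
        new_first = nucleus.id not in self._introduced
        new_second = satellite.id not in self._introduced
        if new_first and new_second:
            first = self.clause(nucleus)
            second = self._embed(self.clause(satellite))
            return f"{first}, and {second}"
        subject = nucleus if new_first else satellite
        return self.clause(subject)

    # -- documents --------------------------------------------------------

    @staticmethod
    def _finish(sentence: str) -> str:
        sentence = sentence.strip()
        for index, char in enumerate(sentence):
            if char.isalpha():
                sentence = sentence[:index] + char.upper() + sentence[index + 1:]
                break
        if not sentence.endswith("."):
            sentence += "."
        return sentence

    def realise(self, plan: DocumentPlan) -> RealisedReport:
        paragraphs: list[str] = []
        for p, paragraph in enumerate(plan.paragraphs):
            sentences: list[str] = []
            for s, sentence in enumerate(paragraph.sentences):
                self._coords = (p, s)
                if isinstance(sentence, Message):
                    text = self.message_text(sentence)
                else:
                    text = self.link_text(sentence)
                sentences.append(self._finish(text))
            paragraphs.append(" ".join(sentences))
        return RealisedReport(text="\n\n".join(paragraphs), mentions=list(self._mentions))


def realise_message(message: Message, lexicon: Optional[Lexicon] = None) -> str:
    """Realise one message as a clause with a fresh mention registry."""
    return Realiser(lexicon=lexicon).message_text(message)


def realise_link(link: RhetoricalLink, lexicon: Optional[Lexicon] = None) -> str:
    """Realise one rhetorical link as a finished sentence."""
    realiser = Realiser(lexicon=lexicon)
    return realiser._finish(realiser.link_text(link))


def realise_document(
    plan: DocumentPlan,
    lexicon: Optional[Lexicon] = None,
    grammar: Optional[Grammar] = None,
) -> str:
    """Realise a whole plan deterministically; paragraphs separated by blank
    lines, sentences capitalised and terminated."""
    return Realiser(lexicon=lexicon, grammar=grammar).realise(plan).text
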