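# Methods

This note records the model behind `chronica`, the parameters that matter,
the behaviour of the synthetic data the tests run on, and the design
decisions taken where more than one reasonable choice existed.

## The chronicle model

A chronicle is a typed directed multigraph of clinical events. The event
class set is closed (`Diagnosis`, `Investigation`, `Intervention`,
`Prescription`, `ClinicalProblem`) because realisation templates key on the
class; the subtype vocabulary is open because lexical choice keys on the
subtype and must absorb new vocabulary without rule changes. Relations are
`inference` (an investigation revealed a finding), `cause` (a problem led
to a treatment), `elaboration` and `follows`. The cause/inference subgraph
must be acyclic — a finding cannot transitively cause its own discovery —
and this is checked via strongly connected components; `elaboration` and
`follows` edges are exempt (temporal annotation can legitimately run
against causal direction).

Dates are day- or month-precision, with the year optional; precision is
explicit in the serialised form (`{"date": "--10-15", "precision": "day"}`,
using the ISO 8601 year-truncated form for year-less dates). Events may be
undated. Chronicles serialise to canonical JSON — sorted keys, fixed date
form, trailing newline — so equality of chronicles coincides with equality
of bytes; event list order is preserved, as it is the tie-break of last
resort in chronological ordering.

## Ordering: one rule everywhere

Every stage that orders events uses the same rule. An event's *effective
date* is its own start date; an undated event borrows the date of its
nearest dated relation neighbour (fewest undirected hops; among equally
near, the earliest date). Dated events sort by (effective date, fixed class
order, id), where the class order is Diagnosis, Investigation,
Intervention, Prescription, ClinicalProblem; events with no effective date
go last in input order. Month-precision dates sort before any day of the
same month. The neighbour-borrowing rule is what places an undated
diagnosis finding next to the investigation that revealed it rather than at
the end of the report.

Under a period filter, an event is kept iff its effective date exists and
falls inside the period: membership of an undatable event in a time window
cannot be established, so it is excluded.

## Content selection

`extract_spine` is a linear filter (class match; subtype match when the
focus names one; period) followed by the shared sort. `expand_elaborations`
runs one breadth-first search per spine event over the undirected relation
graph up to `depth` hops. Traversal is undirected because a problem-focused
summary must pull in both the investigation that revealed the problem (an
incoming inference edge) and the treatment it caused (an outgoing cause
edge). An event reachable from several spine events is attached to exactly
one — the nearest, with ties going to the earlier spine position — so no
event is narrated twice. The relation path from spine to elaboration is
recorded. Longitudinal selection makes every event principal (no
elaborations) and carries all relations among selected events.

`depth` is exposed directly as an integer (default 1); any mapping from a
requested summary "size" to a depth is left to callers.

## Microplanning

The domain→RST mapping is total and fixed: inference → *result*, cause →
*cause*, elaboration → *elaboration*, follows → *sequence*.

Aggregation is conceptual only and operationalised as the strictest
predicate consistent with never generalising: only maximal runs of ≥2
consecutive mentions with an identical (class, subtype) merge, carrying
every member's date. Distinct subtypes never merge, so "chemotherapy
course" followed by "radiotherapy course" stays two mentions.

One paragraph is planned per (possibly aggregated) spine entry. Within a
paragraph, elaborations are ordered chronologically; an elaboration with a
direct relation to the spine event realises *through* that relation as a
rhetorical link, and the first such link doubles as the spine event's
introduction (producing the relative-clause sentence shape). At most one
rhetorical link is packed per sentence; longer chains split across
sentences. An aggregated spine group always states itself first, since a
link can introduce only an individual event.

A spine event with no elaborations (the longitudinal case) but with a
carried relation to an already-introduced event realises through that link
with a definite back-reference ("The biopsy revealed cancer of the left
breast."). This is the package's resolution of a genuine tension: the plan
introduces every event exactly once, yet the carried relations should
surface in the text. Exactly-once therefore applies to *introducing*
mentions; links may re-reference introduced events, which the realiser
renders as definite noun phrases.

## Realisation

Two rule families, both shipped as editable YAML data:

* `data/grammar.yaml` — generic phrase and sentence patterns (definite noun
  phrase = article + noun; causal sentence = main clause + causal connector
  + subordinate phrase; ...) plus the discourse connectives ("because of",
  "which revealed", "Subsequently"). These never change with vocabulary.
* `data/lexicon.yaml` — per-class clause templates (verb group, article
  policy) with subtype overrides. Lookup falls back from (class, subtype)
  to the class default, which is what makes an unseen subtype of a known
  class realise correctly with no edits.

Referring expressions use a per-document mention registry: first mention is
full (indefinite or bare by article policy, with locus post-modifier and
label parenthetical), later mentions are definite head nouns. A locus
post-modifier on a link's satellite is suppressed when the nucleus of the
same sentence already expressed the same locus (a biopsy of the left breast
reveals "cancer", not "cancer of the left breast"). The registry doubles as
an instrumentation trace: every realised mention is recorded with its
sentence coordinates, so tests can verify that the set of events mentioned
in the text equals the selected content exactly.

Date phrases follow British convention: "On 15th October" (ordinal day,
year only when present), "In October 2001" for month precision. Aggregated
mentions realise with a count, a pluralised head noun and conjoined bare
date phrases: "the patient had 3 blood transfusions (on 1st March, 2nd
April, and 3rd May)". Pluralisation is suffix-based with an irregular-form
override field in the lexicon; nothing deeper is attempted.

Output is plain text or Markdown with a metadata header; no richer
formatting layer is produced.

## Synthetic data

The generator emulates the *shape* of an oncology record: consultations
spread over a configurable horizon, each contributing 1–3 events drawn from
a class mix, with subtype vocabularies per class and attributes (locus,
course labels CC*n*/RC*n*, transfusion content, diagnosis stage) attached
where they make sense. Defaults describe a short record — 8 consultations
over 12 months — with class mix 10% diagnoses, 30% investigations, 20%
interventions, 25% prescriptions, 15% clinical problems, 1.2 relations per
event and a 10% missing-date rate; these are one-off choices of a
plausible oncology record shape, not tuned quantities. Edge types respect
the clinical direction constraints (inference: Investigation →
Problem/Diagnosis; cause: Problem/Diagnosis → Intervention/Prescription),
which incidentally guarantees causal acyclicity by construction, and
directed clinical edges never point backwards in time. One
`random.Random(seed)` instance drives all draws; no global state.

What the generator does **not** emulate: real treatment protocols, coded
terminologies, free-text noise, multi-year relapse structure, or
inconsistent/conflicting dates. Passing tests therefore demonstrate the
correctness of selection, planning and realisation over well-formed event
graphs — not robustness to the extraction errors a chronicle built from
real narratives would contain.

## Numerical and degenerate-input choices

* Empty chronicle, empty spine, empty paragraph: all legal, producing an
  empty report body under its header.
* Same-date ties: fixed class order, then id — fully deterministic.
* A focus matching nothing yields an empty (valid) report; a
  perspective/user-defined request with no focus at all is an error.
* Violations are collected, not thrown: validation reports every broken
  invariant of a file in one pass.
* Test problem sizes: property suites run on 120–500 generated chronicles
  of ≤40 events and 1000 random message lists, sizes at which the
  brute-force oracles are still exact and the full suite stays fast.

## Known limitations

* No referring-expression planning across paragraphs beyond definiteness
  (no pronouns, no "this course").
* No syntactic aggregation ("had a biopsy and an X-ray"); aggregation is
  conceptual only.
* Morphology is limited to simple pluralisation; verb forms are stored
  inflected in the lexicon.
* Only point/interval calendar dates are modelled; richer temporal
  abstractions (e.g. "three weeks after surgery") are out of scope.
* English only; the genre lexis ("underwent", "was prescribed") is fixed in
  the default lexicon but overridable.
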