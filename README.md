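# chronica

**English summary reports from semantic graphs of clinical events.**

Clinicians typically have minutes, not hours, to get to know an unfamiliar
patient's history, and that history often lives in dozens of letters,
discharge summaries and results. When a record is instead encoded as data —
a *chronicle*: the patient's clinical events plus the inferential, causal
and temporal links between them — a natural-language generator can turn it
into a short, coherent textual overview on demand. `chronica` is such a
generator: it produces full longitudinal summaries, perspective summaries
focused on one kind of event (clinical problems, curative procedures, ...)
and user-defined selections, for users such as GPs and hospital clinicians
preparing for a consultation.

## The model

A chronicle is a directed graph. Nodes are typed clinical events
(`Diagnosis`, `Investigation`, `Intervention`, `Prescription`,
`ClinicalProblem`), each with an open subtype ("biopsy", "CT scan",
"chemotherapy course", ...), a feature map (anatomical locus, course label,
content) and an optional day- or month-precision date. Edges are typed
relations: *inference* (a biopsy reveals cancer), *cause* (cancer leads to
chemotherapy), *elaboration* and *follows*.

Report generation follows the classical three-stage NLG pipeline:

1. **Content selection** — extract the *spine*: the chronologically ordered
   events matching the requested focus; then attach every event within
   `depth` relation hops as an elaboration (depth 0 lists the focused
   events alone; depth 1 adds, e.g., the treatment a diagnosis caused, but
   nothing further). Longitudinal reports make every event principal,
   ordered by date and, within a date, by a fixed class order.
2. **Microplanning** — map domain relations to rhetorical relations of
   Rhetorical Structure Theory (inference → *result*, cause → *cause*,
   elaboration → *elaboration*, follows → *sequence*); aggregate runs of
   repeated events with the same class *and* subtype into one mention
   (conceptual aggregation only — two different drugs never become "two
   drugs"); plan one paragraph per spine entry, packing a spine event and a
   directly linked elaboration into a single sentence via their rhetorical
   link.
3. **Surface realisation** — a generic phrase/sentence grammar (definite
   noun phrase = article + noun; causal sentence = main clause + causal
   connector + subordinate phrase; ...) plus a domain lexicon of clause
   templates keyed by event class with subtype overrides. *Result* links
   realise as "... which revealed X", *cause* links with the connective
   "because of". First mentions are full and indefinite, later mentions
   definite ("the cancer"). Because lookup falls back to the class entry,
   brand-new vocabulary of a known class ("mastectomy") realises with no
   rule edits.

No real patient data is included or required: a seeded synthetic generator
produces structurally realistic oncology chronicles for testing and demos.

## Worked example

The packaged three-event vignette (`examples/worked_example.chronicle.json`)
contains a biopsy of the left breast on 15th October, the cancer it
revealed, and a chemotherapy course (CC1) started on 1st December because
of the cancer:

```sh
$ chronica generate examples/worked_example.chronicle.json \
    --kind perspective --focus ClinicalProblem --depth 1
patient: example
kind: perspective
focus: ClinicalProblem
depth: 1
period: all
generator: chronica 0.1.0
----------------------------------------
On 15th October, the patient had a biopsy of the left breast which revealed cancer. On 1st December, the patient started a chemotherapy course (CC1) because of the cancer.
```

The paragraph is the depth-1 perspective on clinical problems: the spine is
the single problem (the cancer), sentence one realises the *result* link
from the biopsy that revealed it, sentence two the *cause* link to the
chemotherapy it triggered — note the definite back-reference "the cancer".

Other commands:

```sh
chronica synth --seed 7 --consultations 8 --months 12 -o patient.json
chronica validate patient.json
chronica generate patient.json --kind longitudinal -o report.txt
chronica generate patient.json --preset procedures --depth 1
```

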