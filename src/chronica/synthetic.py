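"""Seeded generator of synthetic oncology chronicles.

No real patient data ships with this package; every pipeline stage is
exercised on generated chronicles instead.  The generator emulates the
*shape* of an oncology record — a run of consultations spread over months
or years, each contributing a handful of typed events, with inference
edges from investigations to the problems they reveal and cause edges
from problems to the treatments they trigger.  Clinical plausibility is
structural only: edge types respect those class constraints, but no real
treatment protocol is modelled.

Determinism contract: one top-level seed drives a private
:class:`random.Random`; no global random state is touched, and the same
config always yields a byte-identical chronicle.
"""

from __future__ import annotations

import random
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import (
    Chronicle,
    DateSpan,
    Event,
    EventClass,
    PartialDate,
    Relation,
    RelationType,
)

__all__ = ["GeneratorConfig", "generate_chronicle", "worked_example_chronicle"]

# Open subtype vocabulary, oncology-flavoured.
SUBTYPES: dict[EventClass, tuple[str, ...]] = {
    EventClass.DIAGNOSIS: (
        "breast carcinoma",
        "invasive ductal carcinoma",
        "bony metastases",
        "lymphoma",
    ),
    EventClass.INVESTIGATION: (
        "biopsy",
        "CT scan",
        "X-ray",
        "blood test",
        "MRI scan",
        "ultrasound",
    ),
    EventClass.INTERVENTION: (
        "surgery",
        "chemotherapy course",
        "radiotherapy course",
        "blood transfusion",
    ),
    EventClass.PRESCRIPTION: (
        "tamoxifen",
        "morphine",
        "antibiotics",
        "iron supplement",
    ),
    EventClass.CLINICAL_PROBLEM: (
        "cancer",
        "anaemia",
        "pain",
        "nausea",
        "infection",
    ),
}

_LOCI = ("left breast", "right breast", "left lung", "liver", "spine", "pelvis")
_STAGES = ("I", "II", "III", "IV")

# Classes whose events may carry an anatomical locus.
_LOCUS_CLASSES = {
    EventClass.INVESTIGATION,
    EventClass.CLINICAL_PROBLEM,
    EventClass.DIAGNOSIS,
    EventClass.INTERVENTION,
}

#: Legal (source classes, target classes) for the directed clinical edges.
INFERENCE_SOURCES = {EventClass.INVESTIGATION}
INFERENCE_TARGETS = {EventClass.CLINICAL_PROBLEM, EventClass.DIAGNOSIS}
CAUSE_SOURCES = {EventClass.CLINICAL_PROBLEM, EventClass.DIAGNOSIS}
CAUSE_TARGETS = {EventClass.INTERVENTION, EventClass.PRESCRIPTION}

_DEFAULT_MIX = {
    EventClass.DIAGNOSIS: 0.10,
    EventClass.INVESTIGATION: 0.30,
    EventClass.INTERVENTION: 0.20,
    EventClass.PRESCRIPTION: 0.25,
    EventClass.CLINICAL_PROBLEM: 0.15,
}


class GeneratorConfig(BaseModel):
    """Knobs for the synthetic chronicle generator.

    Defaults mirror a short oncology record: 8 consultations over one
    year.  ``class_mix`` weights the event classes drawn at each
    consultation; ``relation_density`` is the expected number of relations
    per event; ``missing_date_rate`` is the probability that an event
    carries no usable date.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_consultations: int = Field(default=8, ge=0)
    duration_months: int = Field(default=12, ge=1)
    class_mix: dict[EventClass, float] = Field(
        default_factory=lambda: dict(_DEFAULT_MIX)
    )
    relation_density: float = Field(default=1.2, ge=0.0)
    missing_date_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    start_year: int = Field(default=2001, ge=1, le=9999)

    @model_validator(mode="after")
    def _mix_valid(self) -> "GeneratorConfig":
        if any(w < 0 for w in self.class_mix.values()):
            raise ValueError("class_mix weights must be non-negative")
        if not any(w > 0 for w in self.class_mix.values()):
            raise ValueError("class_mix weights must not all be zero")
        return self


def _draw_class(rng: random.Random, mix: dict[EventClass, float]) -> EventClass:
    classes = [c for c in EventClass if mix.get(c, 0.0) > 0]
    weights = [mix[c] for c in classes]
    return rng.choices(classes, weights=weights, k=1)[0]


def _make_date(rng: random.Random, config: GeneratorConfig, day_offset: int) -> PartialDate:
    year = config.start_year + day_offset // 365
    remainder = day_offset % 365
    month = min(12, remainder // 30 + 1)
    day = min(28, remainder % 30 + 1)
    if rng.random() < 0.1:  # occasional month-precision date
        return PartialDate(year=year, month=month)
    return PartialDate(year=year, month=month, day=day)


def _attributes(
    rng: random.Random, event_class: EventClass, subtype: str, chemo_count: int
) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if event_class in _LOCUS_CLASSES and subtype != "blood transfusion" and rng.random() < 0.5:
        attrs["locus"] = rng.choice(_LOCI)
    if subtype == "chemotherapy course":
        attrs["label"] = f"CC{chemo_count}"
    elif subtype == "radiotherapy course":
        attrs["label"] = f"RC{chemo_count}"
    elif subtype == "blood transfusion":
        units = rng.randint(1, 3)
        attrs["content"] = f"{units} unit{'s' if units > 1 else ''} of red cells"
    if event_class is EventClass.DIAGNOSIS and rng.random() < 0.5:
        attrs["stage"] = rng.choice(_STAGES)
    return attrs


def generate_chronicle(config: GeneratorConfig) -> Chronicle:
    """Generate a validating chronicle from a seeded config.

    Guarantees: deterministic per seed; every dated event lies inside the
    configured duration; at least one Diagnosis exists whenever there is at
    least one consultation; inference edges run Investigation →
    ClinicalProblem/Diagnosis and cause edges ClinicalProblem/Diagnosis →
    Intervention/Prescription only (which also keeps the cause/inference
    subgraph acyclic by construction).
    """
    rng = random.Random(config.seed)
    horizon_days = max(1, int(config.duration_months * 30.44))

    offsets = sorted(rng.randrange(horizon_days) for _ in range(config.n_consultations))

    events: list[Event] = []
    chemo_count = 0
    for consult_index, offset in enumerate(offsets):
        for _ in range(rng.randint(1, 3)):
            event_class = _draw_class(rng, config.class_mix)
            subtype = rng.choice(SUBTYPES[event_class])
            if subtype in ("chemotherapy course", "radiotherapy course"):
                chemo_count += 1
            time: Optional[DateSpan]
            if rng.random() < config.missing_date_rate:
                time = None
            else:
                time = DateSpan(start=_make_date(rng, config, offset))
            events.append(
                Event(
                    id=f"e{len(events) + 1:03d}",
                    event_class=event_class,
                    subtype=subtype,
                    attributes=_attributes(rng, event_class, subtype, chemo_count),
                    time=time,
                )
            )

    if events and not any(e.event_class is EventClass.DIAGNOSIS for e in events):
        # A record with consultations always names at least one diagnosis.
        index = rng.randrange(len(events))
        old = events[index]
        events[index] = Event(
            id=old.id,
            event_class=EventClass.DIAGNOSIS,
            subtype=rng.choice(SUBTYPES[EventClass.DIAGNOSIS]),
            attributes={},
            time=old.time,
        )

    relations = _draw_relations(rng, events, config)
    return Chronicle(
        patient_id=f"synth-{config.seed}", events=events, relations=relations
    )


def _date_ok(src: Event, tgt: Event) -> bool:
    """Directed clinical edges never point backwards in time."""
    if src.start_date is None or tgt.start_date is None:
        return True
    return src.start_date.sort_key() <= tgt.start_date.sort_key()


def _draw_relations(
    rng: random.Random, events: list[Event], config: GeneratorConfig
) -> list[Relation]:
    candidates: list[tuple[RelationType, str, str]] = []
    for src in events:
        for tgt in events:
            if src.id == tgt.id:
                continue
            if (
                src.event_class in INFERENCE_SOURCES
                and tgt.event_class in INFERENCE_TARGETS
                and _date_ok(src, tgt)
            ):
                candidates.append((RelationType.INFERENCE, src.id, tgt.id))
            if (
                src.event_class in CAUSE_SOURCES
                and tgt.event_class in CAUSE_TARGETS
                and _date_ok(src, tgt)
            ):
                candidates.append((RelationType.CAUSE, src.id, tgt.id))

    dated = [e for e in events if e.start_date is not None]
    dated.sort(key=lambda e: (e.start_date.sort_key(), e.id))  # type: ignore[union-attr]
    for first, second in zip(dated, dated[1:]):
        candidates.append((RelationType.FOLLOWS, first.id, second.id))
        if rng.random() < 0.2:
            candidates.append((RelationType.ELABORATION, first.id, second.id))

    rng.shuffle(candidates)
    n_target = round(config.relation_density * len(events))
    chosen: list[Relation] = []
    seen: set[tuple[RelationType, str, str]] = set()
    for relation_type, src, tgt in candidates:
        if len(chosen) >= n_target:
            break
        key = (relation_type, src, tgt)
        if key in seen:
            continue
        seen.add(key)
        chosen.append(Relation(source=src, target=tgt, relation_type=relation_type))
    return chosen


def worked_example_chronicle() -> Chronicle:
    """The fixed three-event breast-cancer vignette.

    A biopsy of the left breast on 15th October reveals cancer; the cancer
    leads to a chemotherapy course (CC1) started on 1st December.  The
    dates carry no year.  This tiny chronicle anchors the golden
    end-to-end test of the whole pipeline.
    """
    biopsy = Event(
        id="biopsy",
        event_class=EventClass.INVESTIGATION,
        subtype="biopsy",
        attributes={"locus": "left breast"},
        time=DateSpan(start=PartialDate(month=10, day=15)),
    )
    cancer = Event(
        id="cancer",
        event_class=EventClass.CLINICAL_PROBLEM,
        subtype="cancer",
        attributes={"locus": "left breast"},
    )
    chemo = Event(
        id="chemo1",
        event_class=EventClass.INTERVENTION,
        subtype="chemotherapy course",
        attributes={"label": "CC1"},
        time=DateSpan(start=PartialDate(month=12, day=1)),
    )
    return Chronicle(
        patient_id="example",
        events=[biopsy, cancer, chemo],
        relations=[
            Relation(source="biopsy", target="cancer", relation_type=RelationType.INFERENCE),
            Relation(source="cancer", target="chemo1", relation_type=RelationType.CAUSE),
        ],
    )
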