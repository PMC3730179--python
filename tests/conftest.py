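"""Shared fixtures: the worked example, random chronicles and requests."""

from __future__ import annotations

import random
from pathlib import Path

import pytest

from chronica.model import (
    Chronicle,
    DateSpan,
    EventClass,
    FocusSpec,
    PartialDate,
    ReportKind,
    ReportRequest,
)
from chronica.synthetic import (
    SUBTYPES,
    GeneratorConfig,
    generate_chronicle,
    worked_example_chronicle,
)

EXAMPLE_FILE = Path(__file__).resolve().parent.parent / "examples" / "worked_example.chronicle.json"

GOLDEN_PARAGRAPH = (
    "On 15th October, the patient had a biopsy of the left breast which "
    "revealed cancer. On 1st December, the patient started a chemotherapy "
    "course (CC1) because of the cancer."
)


def make_random_chronicle(seed: int) -> Chronicle:
    """A varied, always-valid chronicle of at most 40 events."""
    rng = random.Random(seed)
    config = GeneratorConfig(
        seed=seed,
        n_consultations=rng.randint(0, 13),
        duration_months=rng.randint(1, 24),
        relation_density=rng.uniform(0.0, 2.5),
        missing_date_rate=rng.uniform(0.0, 0.4),
    )
    return generate_chronicle(config)


def make_random_request(seed: int) -> ReportRequest:
    """A random perspective/user-defined request, sometimes with a period."""
    rng = random.Random(seed ^ 0x5EED)
    event_class = rng.choice(list(EventClass))
    subtype = rng.choice((None,) + SUBTYPES[event_class]) if rng.random() < 0.4 else None
    period = None
    if rng.random() < 0.3:
        start = PartialDate(year=2001, month=rng.randint(1, 6))
        end = PartialDate(year=2001 + rng.randint(0, 1), month=rng.randint(7, 12))
        period = DateSpan(start=start, end=end)
    return ReportRequest(
        kind=ReportKind.PERSPECTIVE,
        focus_classes=[FocusSpec(event_class=event_class, subtype=subtype)],
        depth=rng.randint(0, 3),
        period=period,
    )


@pytest.fixture
def worked() -> Chronicle:
    return worked_example_chronicle()


@pytest.fixture
def problems_request() -> ReportRequest:
    return ReportRequest(
        kind=ReportKind.PERSPECTIVE,
        focus_classes=[FocusSpec(event_class=EventClass.CLINICAL_PROBLEM)],
        depth=1,
    )


@pytest.fixture(scope="session")
def corpus() -> list[Chronicle]:
    """120 seeded chronicles for unit-level property checks."""
    return [make_random_chronicle(seed) for seed in range(120)]
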