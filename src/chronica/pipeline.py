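"""End-to-end report generation: chronicle + request → English text.

Thin glue over the three pipeline stages (select → plan → realise), kept
separate so each stage remains independently testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .microplan import DocumentPlan, plan_document
from .model import Chronicle, ReportRequest
from .realise import Grammar, Lexicon, RealisedReport, Realiser
from .selection import ContentGraph, select_content

__all__ = ["GeneratedReport", "generate_report"]


@dataclass
class GeneratedReport:
    """A realised report together with the intermediate artefacts."""

    text: str
    content: ContentGraph
    plan: DocumentPlan
    realisation: RealisedReport


def generate_report(
    chronicle: Chronicle,
    request: ReportRequest,
    lexicon: Optional[Lexicon] = None,
    grammar: Optional[Grammar] = None,
) -> GeneratedReport:
    """Run the full pipeline and keep every intermediate stage inspectable."""
    content = select_content(chronicle, request)
    plan = plan_document(content, chronicle)
    realisation = Realiser(lexicon=lexicon, grammar=grammar).realise(plan)
    return GeneratedReport(
        text=realisation.text, content=content, plan=plan, realisation=realisation
    )
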