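"""Bit-stable reading and writing of chronicles and generated reports.

Chronicles travel as versioned JSON documents.  Writing is canonical —
sorted object keys, fixed date serialisation, trailing newline — so equal
chronicles always produce identical bytes and a write/read round trip is
the identity.  The JSON schema is published programmatically via
:func:`chronicle_json_schema` (see docs/chronicle-format.md).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Any, Union

import pydantic
from pydantic import BaseModel, ConfigDict, Field

from .model import Chronicle, Violation, validate_chronicle

__all__ = [
    "FORMAT_VERSION",
    "ChronicleDocument",
    "ChronicleError",
    "ChronicleParseError",
    "ChronicleSchemaError",
    "ChronicleValidationError",
    "read_chronicle",
    "write_chronicle",
    "dumps_chronicle",
    "loads_chronicle",
    "write_report",
    "format_report",
    "chronicle_json_schema",
]

FORMAT_VERSION = "1.0"

Source = Union[str, Path, IO[str]]


class ChronicleError(Exception):
    """Base class for chronicle I/O failures."""


class ChronicleParseError(ChronicleError):
    """The input is not well-formed JSON."""


class ChronicleSchemaError(ChronicleError):
    """The JSON does not conform to the chronicle schema.

    ``locations`` holds dotted paths into the document for each offence.
    """

    def __init__(self, message: str, locations: list[str] | None = None) -> None:
        super().__init__(message)
        self.locations = locations or []


class ChronicleValidationError(ChronicleError):
    """The document parsed but breaks a chronicle invariant."""

    def __init__(self, violations: list[Violation]) -> None:
        lines = "; ".join(str(v) for v in violations)
        super().__init__(f"chronicle fails validation: {lines}")
        self.violations = violations


class ChronicleDocument(BaseModel):
    """Top-level JSON container: a format version plus the chronicle."""

    model_config = ConfigDict(extra="forbid")

    format_version: str = Field(default=FORMAT_VERSION)
    chronicle: Chronicle


def _read_text(source: Source) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text(encoding="utf-8")
    return source.read()


def loads_chronicle(text: str) -> Chronicle:
    """Parse and fully validate a chronicle document from a JSON string."""
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ChronicleParseError(f"malformed JSON: {exc}") from exc
    try:
        document = ChronicleDocument.model_validate(raw)
    except pydantic.ValidationError as exc:
        locations = [
            ".".join(str(part) for part in err["loc"]) for err in exc.errors()
        ]
        detail = "; ".join(
            f"{loc}: {err['msg']}" for loc, err in zip(locations, exc.errors())
        )
        raise ChronicleSchemaError(f"schema error: {detail}", locations) from exc
    if document.format_version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise ChronicleSchemaError(
            f"unsupported format_version {document.format_version!r}",
            ["format_version"],
        )
    violations = validate_chronicle(document.chronicle)
    if violations:
        raise ChronicleValidationError(violations)
    return document.chronicle


def read_chronicle(source: Source) -> Chronicle:
    """Read a chronicle from a path or open text stream.

    Raises :class:`ChronicleParseError` for malformed JSON,
    :class:`ChronicleSchemaError` for structural offences (naming the field
    location) and :class:`ChronicleValidationError` when graph invariants
    fail.
    """
    return loads_chronicle(_read_text(source))


def dumps_chronicle(chronicle: Chronicle) -> str:
    """Serialise to canonical JSON text.

    Object keys are sorted and dates use the fixed
    ``{"date": ..., "precision": ...}`` form, so two equal chronicles
    always serialise to identical bytes.  Refuses invalid chronicles.
    """
    violations = validate_chronicle(chronicle)
    if violations:
        raise ChronicleValidationError(violations)
    document = ChronicleDocument(format_version=FORMAT_VERSION, chronicle=chronicle)
    payload = document.model_dump(mode="json")
    return json.dumps(payload, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def write_chronicle(chronicle: Chronicle, dest: Source) -> None:
    """Write canonical chronicle JSON to a path or open text stream."""
    text = dumps_chronicle(chronicle)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)


def format_report(body: str, metadata: dict[str, Any], markdown: bool = False) -> str:
    """Assemble report text: a header block describing the run, then the body.

    ``metadata`` keys are emitted in insertion order; values are rendered
    with ``str``.  In Markdown mode the header is a heading plus a bullet
    list; in plain-text mode a ruled block.  Paragraph breaks in ``body``
    (blank lines) are preserved in both modes.
    """
    lines: list[str] = []
    if markdown:
        title = str(metadata.get("title", "Patient report"))
        lines.append(f"# {title}")
        lines.append("")
        for key, value in metadata.items():
            if key == "title":
                continue
            lines.append(f"- **{key}**: {value}")
        lines.append("")
    else:
        for key, value in metadata.items():
            if key == "title":
                continue
            lines.append(f"{key}: {value}")
        lines.append("-" * 40)
    text = "\n".join(lines)
    body = body.strip("\n")
    if body:
        text += "\n" + body + "\n"
    else:
        text += "\n"
    return text


def write_report(
    body: str,
    metadata: dict[str, Any],
    dest: Source,
    markdown: bool = False,
) -> None:
    """Write a generated report with its header block to ``dest``."""
    text = format_report(body, metadata, markdown=markdown)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)


def chronicle_json_schema() -> dict[str, Any]:
    """JSON Schema for the chronicle document format (draft 2020-12)."""
    return ChronicleDocument.model_json_schema()
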