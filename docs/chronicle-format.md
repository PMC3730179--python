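# Chronicle JSON format (version 1.0)

A chronicle file is a single JSON object:

```json
{
  "format_version": "1.0",
  "chronicle": {
    "patient_id": "example",
    "events": [ ... ],
    "relations": [ ... ]
  }
}
```

The machine-readable JSON Schema is available programmatically:

```python
from chronica.io import chronicle_json_schema
schema = chronicle_json_schema()   # draft 2020-12
```

## Events

```json
{
  "id": "biopsy",
  "event_class": "Investigation",
  "subtype": "biopsy",
  "attributes": {"locus": "left breast"},
  "time": {"start": {"date": "--10-15", "precision": "day"}, "end": null}
}
```

* `id` — unique within the chronicle.
* `event_class` — one of `Diagnosis`, `Investigation`, `Intervention`,
  `Prescription`, `ClinicalProblem` (closed set).
* `subtype` — non-empty free-text category token (open vocabulary).
* `attributes` — optional string map; the realiser understands `locus`,
  `label`, `content` and `stage`.
* `time` — optional; `start` required, `end` optional (intervals must have
  `start` ≤ `end`).

### Dates

Dates carry explicit precision:

| form | meaning |
|------|---------|
| `{"date": "2001-10-15", "precision": "day"}` | full date |
| `{"date": "2001-10", "precision": "month"}` | month precision |
| `{"date": "--10-15", "precision": "day"}` | day precision, year unknown |
| `{"date": "--10", "precision": "month"}` | month precision, year unknown |

The year-less forms use the ISO 8601 year-truncated notation.

## Relations

```json
{"source": "biopsy", "target": "cancer", "relation_type": "inference"}
```

* `relation_type` — `inference`, `cause`, `elaboration` or `follows`.
* Both endpoints must name existing events; no self-relations; at most one
  relation of a given type per ordered pair.
* The subgraph of `inference`+`cause` edges must be acyclic.

## Canonical serialisation

`chronica` writes chronicles with sorted object keys, two-space
indentation, the date forms above and a trailing newline. Equal chronicles
(including event order, which is preserved) always serialise to identical
bytes, and writing then reading is the identity.

## Reports

Generated reports are UTF-8 plain text or Markdown: a header block
(patient id, report kind, focus, depth, period, generator version)
followed by the body, paragraphs separated by blank lines.
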