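{
  "chronicle": {
    "events": [
      {
        "attributes": {
          "locus": "left breast"
        },
        "event_class": "Investigation",
        "id": "biopsy",
        "subtype": "biopsy",
        "time": {
          "end": null,
          "start": {
            "date": "--10-15",
            "precision": "day"
          }
        }
      },
      {
        "attributes": {
          "locus": "left breast"
        },
        "event_class": "ClinicalProblem",
        "id": "cancer",
        "subtype": "cancer",
        "time": null
      },
      {
        "attributes": {
          "label": "CC1"
        },
        "event_class": "Intervention",
        "id": "chemo1",
        "subtype": "chemotherapy course",
        "time": {
          "end": null,
          "start": {
            "date": "--12-01",
            "precision": "day"
          }
        }
      }
    ],
    "patient_id": "example",
    "relations": [
      {
        "relation_type": "inference",
        "source": "biopsy",
        "target": "cancer"
      },
      {
        "relation_type": "cause",
        "source": "cancer",
        "target": "chemo1"
      }
    ]
  },
  "format_version": "1.0"
}
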