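# Domain lexicalisation rules.
#
# `classes` gives the default clause pattern per event class; `subtypes`
# overrides fields for specific subtypes of a class.  A brand-new subtype of
# a known class needs no entry here: it inherits the class default (e.g. a
# "mastectomy" Intervention realises as "the patient underwent a
# mastectomy" with no rule edits).
#
# Entry fields:
#   verb:    past-tense verb group linking "the patient" to the event NP
#   article: "auto" (indefinite, a/an chosen automatically) or "none"
#            (bare NP: mass nouns, proper drug names, "surgery")
#   noun:    overrides the subtype as the NP head noun
#   plural:  irregular plural of the head noun, for aggregated mentions
classes:
  Investigation:
    verb: had
    article: auto
  Intervention:
    verb: underwent
    article: auto
  Prescription:
    verb: was prescribed
    article: none
  Diagnosis:
    verb: was diagnosed with
    article: none
  ClinicalProblem:
    verb: suffered from
    article: none
subtypes:
  Intervention:
    chemotherapy course:
      verb: started
    radiotherapy course:
      verb: started
    surgery:
      article: none
    blood transfusion:
      verb: had
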