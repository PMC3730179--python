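# Generic phrase- and sentence-level grammar.
#
# Each rule expands to an ordered list of constituents; empty constituents
# are dropped and the rest joined.  These rules are domain-independent: new
# clinical vocabulary never requires touching them.
rules:
  definite_noun_phrase: [definite_article, noun]
  indefinite_noun_phrase: [indefinite_article, noun, post_modifier, parenthetical]
  bare_noun_phrase: [noun, post_modifier, parenthetical]
  clause: [subject, verb, object]
  dated_clause: [date_phrase, clause]
  causal_sentence: [main_clause, causal_connector, subordinate_phrase]
  result_sentence: [main_clause, relative_connector, object]
  sequence_sentence: [temporal_connective, main_clause]
connectives:
  cause: because of
  result: which revealed
  sequence: Subsequently,
articles:
  definite: the
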