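# Context cues for the rule-based mention classifier. A cue scopes over
# a candidate in the same sentence within six tokens (before or after
# the candidate span); the nearest cue wins. "?" immediately prefixed to
# a candidate is treated as an uncertainty cue.
negation:
  - "no"
  - "not"
  - "denied"
  - "denies"
  - "denying"
  - "without"
  - "nil"
  - "never"
  - "absent"
  - "none"
  - "free of"
  - "absence of"
uncertainty:
  - "monitoring to see if"
  - "to see if"
  - "likely to"
  - "possible"
  - "possibly"
  - "query"
  - "queried"
  - "unclear"
  - "whether"
irrelevant:
  - "mother"
  - "father"
  - "brother"
  - "sister"
  - "husband"
  - "wife"
  - "son"
  - "daughter"
  - "grandmother"
  - "grandfather"
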