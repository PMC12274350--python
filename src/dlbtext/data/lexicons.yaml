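# Concept lexicons. A trailing "*" on a stem matches any run of word
# characters; a two-word pattern matches the bigram with whitespace
# between the words. visual_hallucinations is a proximity concept: both
# stems must occur in the same sentence within max_gap intervening
# tokens, in either order.
concepts:
  visual_hallucinations:
    proximity:
      stems: ["visual", "hallucinat*"]
      max_gap: 5
  fluctuations:
    patterns: ["fluctuat*"]
  tremor:
    patterns: ["tremor*"]
  bradykinesia:
    patterns: ["bradykines*"]
  bad_dreams:
    patterns: ["bad dream*"]
  nightmares:
    patterns: ["nightmare*"]
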