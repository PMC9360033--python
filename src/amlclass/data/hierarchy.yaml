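# Default class-assignment hierarchy, first match wins (rank 1 at the top).
# Established WHO entities precede the mutation-defined classes; TP53/complex
# precedes trisomies; sAML2 precedes biCEBPA; the final two rules must be
# mNOS and no_events so that the hierarchy is total.
order:
  - APL_t15_17
  - inv16
  - t8_21
  - KMT2A_t11x
  - t6_9
  - inv3
  - TP53_complex
  - trisomies
  - sAML2
  - biCEBPA
  - NPM1
  - sAML1
  - DNMT3A_IDH
  - WT1
  - mNOS
  - no_events
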