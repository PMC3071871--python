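# Per-source pre-weights (0.5-1.5) adjusting for unequal raw score ranges.
# Derived by dividing the published effective weights (3, 1, 1.5, 4, 1, 1, 3.5)
# by the optimal weight matrix [2, 1, 1, 8, 1, 1, 7]; configurable.
preweight:
  association: 1.5
  linkage: 1.0
  expression_human: 1.5
  literature_human: 0.5
  pathway: 1.0
  expression_animal: 1.0
  literature_animal: 0.5
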