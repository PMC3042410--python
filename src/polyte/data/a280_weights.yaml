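# Gradient-fraction A280 weights: proportion of total A280 units in the
# HP, LP and 80S-monosome pools, per strain, averaged over independent
# gradients.  Mutant values sum to 1.001 as determined; used as-is.
WT:
  HP: 0.308
  LP: 0.276
  Mono: 0.416
mutant:
  HP: 0.114
  LP: 0.149
  Mono: 0.738
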