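# Many mutational stages (n = 50, n_c = 34): chronic-infection regime.
model:
  n: 50
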