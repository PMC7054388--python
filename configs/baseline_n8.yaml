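# Baseline: few mutational stages (n = 8), equal seeding, sigma_c = 0.5 sigma.
model:
  n: 8
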