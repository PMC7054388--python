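# Minimal two-stage system for fast tests and solver cross-checks.
model:
  n: 2
solver:
  t_max: 40.0
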