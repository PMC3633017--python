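# Tumour/effector scenario s3: published b, d, s; remaining constants are
# external-source defaults from the non-dimensionalised Kuznetsov model.
model: case1
label: case1-s3
horizon_days: 100
params:
  a: 1.636
  b: 0.002
  n: 1.0
  p: 1.131
  g: 20.19
  m: 0.00311
  d: 0.3743
  s: 0.1181
initial_state:
  T: 50
  E: 5
provenance:
  a: external-default
  n: external-default
  p: external-default
  g: external-default
  m: external-default
  b: published-table
  d: published-table
  s: published-table
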