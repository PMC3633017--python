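# Tumour/effector/IL-2 scenario with the published parameter table.
model: case2
label: case2
horizon_days: 600
params:
  c: 0.05
  mu2: 0.03
  p1: 0.1245
  g1: 20000000
  s1: 0
  a: 0.18
  b: 1.0e-9
  aa: 1
  g2: 100000
  p2: 5
  g3: 1000
  mu3: 10
  s2: 0
initial_state:
  T: 50
  E: 10
  I: 0
provenance:
  c: published-table
  mu2: published-table
  p1: published-table
  g1: published-table
  s1: published-table
  a: published-table
  b: published-table
  aa: published-table
  g2: published-table
  p2: published-table
  g3: published-table
  mu3: published-table
  s2: published-table
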