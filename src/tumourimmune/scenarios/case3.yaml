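# Tumour/effector/IL-2/TGF-beta scenario with the published parameter table.
model: case3
label: case3
horizon_days: 600
params:
  c: 0.035
  gamma: 10
  mu1: 0.03
  p1: 0.1245
  g1: 20000000
  q1: 10
  q2: 0.1121
  a: 0.18
  K: 1.0e+10
  aa: 1
  g2: 100000
  p2: 0.27
  g3: 20000000
  p3: 5
  g4: 1000
  alpha: 0.001
  mu2: 10
  p4: 2.84
  theta: 1000000
  mu3: 10
initial_state:
  T: 1
  E: 1
  I: 10
  S: 0
provenance:
  c: published-table
  gamma: published-table
  mu1: published-table
  p1: published-table
  g1: published-table
  q1: published-table
  q2: published-table
  a: published-table
  K: published-table
  aa: published-table
  g2: published-table
  p2: published-table
  g3: published-table
  p3: published-table
  g4: published-table
  alpha: published-table
  mu2: published-table
  p4: published-table
  theta: published-table
  mu3: published-table
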