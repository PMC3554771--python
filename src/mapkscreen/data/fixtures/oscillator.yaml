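name: oscillator
topology: negative
cv:
  mapkk: 1
  mapk: 1
  m2kp: 0.1
  mkp: 0.1
rates:
  ka_in: 0.1
  ki_in: 0.1
  kf: 30.0
  k-1: 1.0
  kb2: 10.0
  kd2: 0.1
  k2: 1.0
  kb3: 10.0
  kd3: 0.1
  k3: 1.0
  kb-3: 10.0
  kd-3: 0.1
  k-3: 1.0
  kb-2: 10.0
  kd-2: 0.1
  k-2: 1.0
  kb4: 10.0
  kd4: 0.1
  k4: 1.0
  kb5: 10.0
  kd5: 0.1
  k5: 1.0
  kb-5: 10.0
  kd-5: 0.1
  k-5: 1.0
  kb-4: 10.0
  kd-4: 0.1
  k-4: 1.0
expected:
  stimulus: 1.0
  responsive: true
  o_max: 0.8004
  temporal: oscillation
provenance: 'hand-specified: slow input turnover (delay), strong negative feedback
  onto input inactivation, zero-order cascade (high loop gain); sustained oscillation
  at stimulus 1.0'
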