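name: ultrasensitive
topology: none
cv:
  mapkk: 5
  mapk: 5
  m2kp: 0.5
  mkp: 0.5
rates:
  ka_in: 1.0
  ki_in: 1.0
  kf: 0.0
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
  stimulus: 10.0
  responsive: true
  o_max: 0.8021
  temporal: none
  ultrasensitive: true
  gradient: 54.991
  bistable: false
  bistability: 1.0
provenance: 'hand-specified: tight binding drives the dual (de)phosphorylation cycles
  into the zero-order regime'
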