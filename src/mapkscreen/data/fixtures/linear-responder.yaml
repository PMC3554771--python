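name: linear-responder
topology: none
cv:
  mapkk: 1
  mapk: 1
  m2kp: 0.1
  mkp: 0.1
rates:
  ka_in: 1.0
  ki_in: 1.0
  kf: 0.0
  k-1: 1.0
  kb2: 1.0
  kd2: 10.0
  k2: 1.0
  kb3: 1.0
  kd3: 10.0
  k3: 1.0
  kb-3: 1.0
  kd-3: 10.0
  k-3: 1.0
  kb-2: 1.0
  kd-2: 10.0
  k-2: 1.0
  kb4: 1.0
  kd4: 10.0
  k4: 1.0
  kb5: 1.0
  kd5: 10.0
  k5: 1.0
  kb-5: 1.0
  kd-5: 10.0
  k-5: 1.0
  kb-4: 1.0
  kd-4: 10.0
  k-4: 1.0
expected:
  stimulus: 10.0
  responsive: true
  o_max: 0.8709
  temporal: none
  ultrasensitive: true
  gradient: 4.484
  bistable: false
  bistability: 1.0
provenance: 'hand-specified: weak binding / fast dissociation keeps every cycle first-order,
  giving a graded mono-stable response'
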