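name: transient
topology: negative
cv:
  mapkk: 5.0
  mapk: 5.0
  m2kp: 0.5
  mkp: 0.5
rates:
  ka_in: 0.10439136537412022
  ki_in: 0.15327046195536898
  kf: 7.086928338582697
  k-1: 1.703554393739075
  kb2: 0.3266228984392131
  kd2: 0.6332044132504051
  k2: 7.574343623744781
  kb3: 2.0973290770140984
  kd3: 0.9332638729082502
  k3: 0.6304750938925626
  kb-3: 0.37294944428028454
  kd-3: 0.10938052847721379
  k-3: 0.47347575170642997
  kb-2: 1.879218796591492
  kd-2: 0.46182309435517316
  k-2: 0.3715782784455846
  kb4: 0.21662980923802577
  kd4: 1.7499372143653846
  k4: 9.728953920602825
  kb5: 1.0487518847434414
  kd5: 1.1554733230782193
  k5: 1.4908727387162897
  kb-5: 0.1680243347625218
  kd-5: 0.627629506799213
  k-5: 0.10948967111559113
  kb-4: 0.35431208285720184
  kd-4: 6.196890672409276
  k-4: 0.7822908527354724
expected:
  stimulus: 1.0
  responsive: true
  o_max: 0.3382
  temporal: transient
provenance: located by seeded screen over the log-uniform sampling law (seed 555,
  negative feedback, stimulus 1.0); rate vector 43, concentration vector id 33
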