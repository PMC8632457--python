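{
  "all_three": 1,
  "funsim_only": 5,
  "funsim_semsim": 4,
  "netsim_funsim": 0,
  "netsim_only": 7,
  "netsim_semsim": 2,
  "semsim_only": 3
}
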