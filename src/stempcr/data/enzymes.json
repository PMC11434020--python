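{
  "GlaI": {
    "motif": "RCGY",
    "mc_index": 1,
    "strand_mode": "both",
    "cut_offset": 0,
    "end_chemistry": "blunt"
  },
  "MspJI": {
    "motif": "CNNR",
    "mc_index": 0,
    "strand_mode": "either",
    "cut_offset": null,
    "end_chemistry": "5overhang:4"
  },
  "FspEI": {
    "motif": "CC",
    "mc_index": 1,
    "strand_mode": "either",
    "cut_offset": null,
    "end_chemistry": "5overhang:4"
  }
}
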