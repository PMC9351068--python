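{
 "variants": {
  "kept": [
   "chrT:200:A>T",
   "chrT:400:C>G",
   "chrT:500:G>A"
  ],
  "removed": {
   "chrT:100:A>T": "min_depth",
   "chrT:300:C>G": "population_af",
   "chrT:600:G>A": "min_depth"
  }
 },
 "segments": {
  "kept": [
   "S2",
   "S4",
   "S5",
   "S7",
   "S9",
   "S11",
   "S13"
  ],
  "removed": {
   "S1": "logr_threshold",
   "S3": "logr_threshold",
   "S6": "min_length",
   "S8": "end_margin",
   "S10": "end_margin",
   "S12": "centromere_breakpoint"
  }
 },
 "svs": {
  "kept": [
   "S2",
   "S3"
  ],
  "removed": {
   "S1": "min_span",
   "S4": "centromere_breakpoint"
  }
 }
}
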