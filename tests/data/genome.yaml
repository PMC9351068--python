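centromeres:
  chrT:
  - 4000000
  - 4500000
  chrU:
  - 4000000
  - 4500000
chromosomes:
- length: 10000000
  name: chrT
- length: 10000000
  name: chrU
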