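{
  "C": 12.0,
  "H": 1.0078250,
  "D": 2.0141018,
  "N": 14.0030740,
  "O": 15.9949146,
  "P": 30.9737615
}
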