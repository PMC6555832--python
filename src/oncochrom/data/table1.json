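{
  "A0": -0.709110206,
  "A1": 0.689422042,
  "A2": 0.92135143,
  "A3": 0.291658614,
  "A4": -0.153205021,
  "A5": -0.049106574,
  "A6": 0.002409524,
  "A7": 0.00175899,
  "A8": 0.000128287
}
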