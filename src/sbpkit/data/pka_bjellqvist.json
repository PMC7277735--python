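{
 "n_terminus": {
  "default": 7.5,
  "A": 7.59,
  "M": 7.0,
  "S": 6.93,
  "P": 8.36,
  "T": 6.82,
  "V": 7.44,
  "E": 7.7
 },
 "c_terminus": {
  "default": 3.55,
  "D": 4.55,
  "E": 4.75
 },
 "side_chain_acidic": {
  "C": 9.0,
  "D": 4.05,
  "E": 4.45,
  "Y": 10.0
 },
 "side_chain_basic": {
  "H": 5.98,
  "K": 10.0,
  "R": 12.0
 }
}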