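{
 "scales": {
  "chou_helix": {
   "A": 1.42,
   "C": 0.7,
   "D": 1.01,
   "E": 1.51,
   "F": 1.13,
   "G": 0.57,
   "H": 1.0,
   "I": 1.08,
   "K": 1.16,
   "L": 1.21,
   "M": 1.45,
   "N": 0.67,
   "P": 0.57,
   "Q": 1.11,
   "R": 0.98,
   "S": 0.77,
   "T": 0.83,
   "V": 1.06,
   "W": 1.08,
   "Y": 0.69
  },
  "grantham_polarity": {
   "A": 8.1,
   "C": 5.5,
   "D": 13.0,
   "E": 12.3,
   "F": 5.2,
   "G": 9.0,
   "H": 10.4,
   "I": 5.2,
   "K": 11.3,
   "L": 4.9,
   "M": 5.7,
   "N": 11.6,
   "P": 8.0,
   "Q": 10.5,
   "R": 10.5,
   "S": 9.2,
   "T": 8.6,
   "V": 5.9,
   "W": 5.4,
   "Y": 6.2
  },
  "kyte_doolittle": {
   "A": 1.8,
   "C": 2.5,
   "D": -3.5,
   "E": -3.5,
   "F": 2.8,
   "G": -0.4,
   "H": -3.2,
   "I": 4.5,
   "K": -3.9,
   "L": 3.8,
   "M": 1.9,
   "N": -3.5,
   "P": -1.6,
   "Q": -3.5,
   "R": -4.5,
   "S": -0.8,
   "T": -0.7,
   "V": 4.2,
   "W": -0.9,
   "Y": -1.3
  }
 },
 "version": 1
}
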