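{
  "Fp1": ["Fp2", "F7", "F3", "Fz"],
  "Fp2": ["Fp1", "Fz", "F4", "F8"],
  "F7":  ["Fp1", "F3", "T3"],
  "F3":  ["Fp1", "F7", "Fz", "C3"],
  "Fz":  ["Fp1", "Fp2", "F3", "F4", "Cz"],
  "F4":  ["Fp2", "Fz", "F8", "C4"],
  "F8":  ["Fp2", "F4", "T4"],
  "T3":  ["F7", "C3", "T5"],
  "C3":  ["F3", "T3", "Cz", "P3"],
  "Cz":  ["Fz", "C3", "C4", "Pz"],
  "C4":  ["F4", "Cz", "T4", "P4"],
  "T4":  ["F8", "C4", "T6"],
  "T5":  ["T3", "P3", "O1"],
  "P3":  ["C3", "T5", "Pz", "O1"],
  "Pz":  ["Cz", "P3", "P4", "O1", "O2"],
  "P4":  ["C4", "Pz", "T6", "O2"],
  "T6":  ["T4", "P4", "O2"],
  "O1":  ["T5", "P3", "Pz", "O2"],
  "O2":  ["T6", "P4", "Pz", "O1"]
}
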