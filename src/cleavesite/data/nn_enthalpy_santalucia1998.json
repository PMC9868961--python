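{
  "name": "SantaLucia 1998 unified nearest-neighbor dH",
  "units": "kcal/mol",
  "description": "Duplex-formation enthalpy per dinucleotide stack (5'->3' top strand), unified oligonucleotide parameter set.",
  "delta_h": {
    "AA": -7.9,
    "AT": -7.2,
    "TA": -7.2,
    "CA": -8.5,
    "GT": -8.4,
    "CT": -7.8,
    "GA": -8.2,
    "CG": -10.6,
    "GC": -9.8,
    "GG": -8.0,
    "TT": -7.9,
    "TG": -8.5,
    "AC": -8.4,
    "AG": -7.8,
    "TC": -8.2,
    "CC": -8.0
  }
}
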