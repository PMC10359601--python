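{
  "version": "1.0",
  "units": {"dH": "kcal/mol", "dS": "cal/(mol*K)"},
  "comment": "Nearest-neighbor stacks keyed on the probe strand 5'->3'; the Watson-Crick complement strand is implied. Symmetric duplex chemistries (DNA:DNA, RNA:RNA) list all 16 keys with mirrored values.",
  "tables": {
    "RNA_DNA_HYBRID": {
      "probe_alphabet": "RNA",
      "reference": "Sugimoto et al. (1995) Biochemistry 34:11211, RNA/DNA hybrid duplexes",
      "init": [1.9, -3.9],
      "terminal_penalties": {},
      "stacks": {
        "AA": [-7.8, -21.9],
        "AC": [-5.9, -12.3],
        "AG": [-9.1, -23.5],
        "AU": [-8.3, -23.9],
        "CA": [-9.0, -26.1],
        "CC": [-9.3, -23.2],
        "CG": [-16.3, -47.1],
        "CU": [-7.0, -19.7],
        "GA": [-5.5, -13.5],
        "GC": [-8.0, -17.1],
        "GG": [-12.8, -31.9],
        "GU": [-7.8, -21.6],
        "UA": [-7.8, -23.2],
        "UC": [-8.6, -22.9],
        "UG": [-10.4, -28.4],
        "UU": [-11.5, -36.4]
      }
    },
    "DNA_DNA": {
      "probe_alphabet": "DNA",
      "reference": "SantaLucia & Hicks (2004) unified DNA/DNA parameters",
      "init": [0.2, -5.7],
      "terminal_penalties": {"A": [2.2, 6.9], "T": [2.2, 6.9]},
      "stacks": {
        "AA": [-7.6, -21.3],
        "AC": [-8.4, -22.4],
        "AG": [-7.8, -21.0],
        "AT": [-7.2, -20.4],
        "CA": [-8.5, -22.7],
        "CC": [-8.0, -19.9],
        "CG": [-10.6, -27.2],
        "CT": [-7.8, -21.0],
        "GA": [-8.2, -22.2],
        "GC": [-9.8, -24.4],
        "GG": [-8.0, -19.9],
        "GT": [-8.4, -22.4],
        "TA": [-7.2, -21.3],
        "TC": [-8.2, -22.2],
        "TG": [-8.5, -22.7],
        "TT": [-7.6, -21.3]
      }
    },
    "RNA_RNA": {
      "probe_alphabet": "RNA",
      "reference": "Xia et al. (1998) RNA/RNA Watson-Crick parameters",
      "init": [3.61, -1.5],
      "terminal_penalties": {"A": [3.72, 10.5], "U": [3.72, 10.5]},
      "stacks": {
        "AA": [-6.82, -19.0],
        "AC": [-11.4, -29.5],
        "AG": [-10.48, -27.1],
        "AU": [-9.38, -26.7],
        "CA": [-10.44, -26.9],
        "CC": [-13.39, -32.7],
        "CG": [-10.64, -26.7],
        "CU": [-10.48, -27.1],
        "GA": [-12.44, -32.5],
        "GC": [-14.88, -36.9],
        "GG": [-13.39, -32.7],
        "GU": [-11.4, -29.5],
        "UA": [-7.69, -20.5],
        "UC": [-12.44, -32.5],
        "UG": [-10.44, -26.9],
        "UU": [-6.82, -19.0]
      }
    }
  }
}
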