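{
  "id": "xia1998",
  "description": "RNA/RNA Watson-Crick nearest-neighbor free energies at 37 C (kcal/mol), Xia et al. 1998 / Turner 2004 set. Stacks are keyed by the top-strand dinucleotide 5'->3'; the bottom strand is its Watson-Crick complement.",
  "units": "kcal/mol",
  "initiation": 4.09,
  "terminal_au_penalty": 0.45,
  "stacks": {
    "AA": -0.93,
    "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08,
    "AG": -2.08,
    "CA": -2.11,
    "UG": -2.11,
    "GU": -2.24,
    "AC": -2.24,
    "GA": -2.35,
    "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26,
    "CC": -3.26,
    "GC": -3.42
  }
}
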