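{
  "bjellqvist": {
    "comment": "Bjellqvist-style pKa set with fixed terminal pKas. Keys: n_term, c_term, and ionisable side chains. Positive groups: n_term, K, R, H; negative groups: c_term, D, E, C, Y.",
    "n_term": 7.5,
    "c_term": 3.55,
    "positive": {"K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
  },
  "emboss": {
    "comment": "EMBOSS iep defaults, provided as an alternative named set.",
    "n_term": 8.6,
    "c_term": 3.6,
    "positive": {"K": 10.8, "R": 12.5, "H": 6.5},
    "negative": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
  }
}
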