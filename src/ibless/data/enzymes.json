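{
  "BamHI":  {"recognition": "GGATCC",             "cut_top": 1, "cut_bottom": 5},
  "NotI":   {"recognition": "GCGGCCGC",           "cut_top": 2, "cut_bottom": 6},
  "SrfI":   {"recognition": "GCCCGGGC",           "cut_top": 4, "cut_bottom": 4},
  "AsiSI":  {"recognition": "GCGATCGC",           "cut_top": 5, "cut_bottom": 3},
  "I-SceI": {"recognition": "TAGGGATAACAGGGTAAT", "cut_top": 9, "cut_bottom": 5}
}
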