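[
  {"sample_peak": 0, "ref_ids": [], "note": "likely artifact; no reference counterpart"},
  {"sample_peak": 4, "ref_ids": [], "note": "overlap of the tails of the two adjacent peaks; excluded"},
  {"sample_peak": 5, "ref_ids": [5], "note": "DTW offered 5 and 6; visual inspection resolves to 5"},
  {"sample_peak": 10, "ref_ids": [12], "note": "not prominent in reference; matched via secondary reference work"},
  {"sample_peak": 15, "ref_ids": [19, 20], "note": "plateau formed by two unresolved reference peaks"},
  {"sample_peak": 27, "ref_ids": [42], "note": "trailing peak of a four-peak series, visually distinct"}
]
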