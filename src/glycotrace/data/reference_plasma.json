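[
  {"ref_id": 1, "apex_nt": null, "structures": ["A4G4S[6,6,6,6]4"]},
  {"ref_id": 3, "apex_nt": null, "structures": ["A3G3S[3,6,6]3"]},
  {"ref_id": 4, "apex_nt": null, "structures": ["A2G2S[6,6]2"]},
  {"ref_id": 5, "apex_nt": null, "structures": ["A3F1G3S[3,6,6]3"]},
  {"ref_id": 6, "apex_nt": null, "structures": ["A2G2S[3,6]2"]},
  {"ref_id": 7, "apex_nt": null, "structures": ["FA2G2S[6,6]2"]},
  {"ref_id": 9, "apex_nt": null, "structures": ["A1[3]G1S[3]1", "FA2G2S[3,6]2"]},
  {"ref_id": 11, "apex_nt": null, "structures": ["FA2G2S[3,3]2", "A4G4S[3,3,6]3"]},
  {"ref_id": 12, "apex_nt": null, "structures": ["FA1[3]G1S[6]1", "FA1[6]G1S[3]1", "A2[6]G1S[6]1"]},
  {"ref_id": 15, "apex_nt": null, "structures": ["A4G4S[3,3,3]3"]},
  {"ref_id": 16, "apex_nt": null, "structures": ["A3G3S[6,6]2"]},
  {"ref_id": 17, "apex_nt": null, "structures": ["A3G3S[3,6]2"]},
  {"ref_id": 18, "apex_nt": null, "structures": ["A3G3S[3,6]2"]},
  {"ref_id": 19, "apex_nt": null, "structures": ["A3F1G3S2", "A3F1G3S[6,6]2", "FA2G1S[6]1", "FA3G3S[6,6]2"]},
  {"ref_id": 20, "apex_nt": null, "structures": ["A3F1G3S2", "A3F1G3S[6,6]2", "FA2G1S[6]1", "FA3G3S[6,6]2"]},
  {"ref_id": 22, "apex_nt": null, "structures": ["A2G2S[6]1", "FA2[6]BG1S[6]1"]},
  {"ref_id": 25, "apex_nt": null, "structures": ["FA2G2S[6]1", "M5"]},
  {"ref_id": 26, "apex_nt": null, "structures": ["FA2BG2S[6]1", "FA2[6]G2S[3]1"]},
  {"ref_id": 27, "apex_nt": null, "structures": ["FA2[3]G2S[3]1"]},
  {"ref_id": 30, "apex_nt": null, "structures": ["M6", "A3G3S[6]1"]},
  {"ref_id": 31, "apex_nt": null, "structures": ["FA2", "A3G3S[6]1"]},
  {"ref_id": 32, "apex_nt": null, "structures": ["A2[6]G1"]},
  {"ref_id": 35, "apex_nt": null, "structures": ["FA2B"]},
  {"ref_id": 39, "apex_nt": null, "structures": ["FA2[6]G1"]},
  {"ref_id": 40, "apex_nt": null, "structures": ["FA2[3]G1"]},
  {"ref_id": 41, "apex_nt": null, "structures": ["A2G2", "FA2[6]BG1"]},
  {"ref_id": 42, "apex_nt": null, "structures": ["M8", "FA2[3]BG1"]},
  {"ref_id": 45, "apex_nt": null, "structures": ["FA2G2", "M9"]},
  {"ref_id": 46, "apex_nt": null, "structures": ["FA2BG2"]}
]
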