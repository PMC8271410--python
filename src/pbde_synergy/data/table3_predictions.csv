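molecule_id,CM,PM,MM
BDEs-3,74.645,54.702,53.951
BDEs-3-1,90.157,60.395,59.704
BDEs-3-2,75.509,61.094,68.707
BDEs-3-3,95.499,51.523,70.958
BDEs-3-4,96.828,57.677,63.680
BDEs-3-5,95.060,57.280,62.087
BDEs-3-6,77.446,55.847,61.235
BDEs-3-7,104.713,63.826,72.277
BDEs-3-8,106.414,58.210,63.680
BDEs-3-9,81.846,59.429,72.444
BDEs-3-10,107.399,57.810,62.087
BDEs-3-11,65.464,65.013,73.961
BDEs-3-12,32.885,61.518,70.469
BDEs-3-13,100.231,60.395,63.096
BDEs-3-14,30.409,45.082,51.880
BDEs-3-15,30.409,45.082,51.880
BDEs-3-16,30.409,45.082,51.880
BDEs-3-17,30.409,45.082,51.880
BDEs-3-18,30.409,45.082,51.880
BDEs-3-19,90.910,68.479,68.345
BDEs-3-20,30.409,45.082,51.880
BDEs-3-21,30.409,45.082,51.880
BDEs-3-22,30.409,45.082,51.880
BDEs-3-23,30.409,45.082,51.880
BDEs-3-24,30.409,45.082,51.880
BDEs-3-25,30.409,45.082,51.880
BDEs-3-26,30.409,45.082,51.880
BDEs-3-27,30.409,45.082,51.880
BDEs-3-28,30.409,45.082,51.880
BDEs-3-29,30.409,45.082,51.880
BDEs-3-30,84.333,54.200,64.863
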