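molecule_id,cbr_bde_kcal_mol,ec50_mg_l,log_bcf,vp_pa,insoluble
BDEs-3,95.378,0.799,5.91,0.109,0
BDEs-3-1,95.965,11.362,0.50,1.68e-5,1
BDEs-3-2,95.630,1620.691,0.50,9.30e-10,1
BDEs-3-4,96.191,0.353,3.29,1.07e-2,0
BDEs-3-5,96.199,0.170,3.61,3.81e-3,0
BDEs-3-6,96.215,0.092,3.89,2.74e-3,0
BDEs-3-7,96.264,0.047,4.19,1.26e-3,0
BDEs-3-8,96.258,0.992,2.32,6.34e-4,0
BDEs-3-9,96.090,2.029,2.61,2.67e-4,0
BDEs-3-10,96.357,1.609,2.68,1.48e-3,0
BDEs-3-13,96.027,0.573,3.10,2.30e-3,0
BDEs-3-19,95.785,0.417,2.82,3.52e-4,0
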