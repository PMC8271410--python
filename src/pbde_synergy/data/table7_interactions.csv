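ligand,receptor,residue,distance_A,bond_type
BDEs-3,1CNF,LEU23,5.14,Alkyl
BDEs-3,1CNF,LEU23,5.14,P-Alkyl
BDEs-3,1CNF,VAL27,4.07,P-Alkyl
BDEs-3,1CNF,VAL27,4.56,P-Alkyl
BDEs-3,1CNF,LEU79,4.77,Alkyl
BDEs-3,1CNF,LYS81,4.94,P-Alkyl
BDEs-3,1CNF,ASP180,3.39,P-Anion
BDEs-3,1CNF,LEU182,4.79,P-Alkyl
BDEs-3,1CNF,LEU183,4.71,Alkyl
BDEs-3-19,1CNF,PHE91,5.32,P-Alkyl
BDEs-3-19,1CNF,CYS242,3.42,Br
BDEs-3-19,1CNF,CYS242,4.16,Alkyl
BDEs-3-19,1CNF,PRO244,4.62,P-Alkyl
BDEs-3-19,1CNF,PRO245,4.55,P-Alkyl
BDEs-3-19,1CNF,FAD271,3.76,P-Alkyl
BDEs-3-19,1CNF,FAD271,4.13,P-Alkyl
BDEs-3-19,1CNF,FAD271,3.58,P-Donor
BDEs-3,1L7V,PRO84,3.77,P-Alkyl
BDEs-3,1L7V,PRO84,5.17,P-Alkyl
BDEs-3,1L7V,LEU85,4.91,P-Alkyl
BDEs-3,1L7V,PHE86,4.77,P-P
BDEs-3-19,1L7V,PRO84,3.83,P-Alkyl
BDEs-3-19,1L7V,LEU85,4.76,Alkyl
BDEs-3-19,1L7V,ALA215,3.17,Br
BDEs-3-19,1L7V,LEU147,4.54,Alkyl
BDEs-3-19,1L7V,THR83,3.85,P-Sigma
BDEs-3-19,1L7V,PRO85,3.27,Br
BDEs-3-19,1L7V,PRO85,4.14,Alkyl
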