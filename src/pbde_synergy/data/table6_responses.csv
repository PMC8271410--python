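run,A,D,F,G,system,binding_energy_kj_mol
0,0,0,0,0,plant,-39.964
0,0,0,0,0,microbe,-10.186
1,0,1,0,1,plant,
1,0,1,0,1,microbe,-26.891
2,0,0,1,0,plant,
2,0,0,1,0,microbe,
3,0,1,1,0,plant,
3,0,1,1,0,microbe,-5.009
4,1,1,0,0,plant,-15.999
4,1,1,0,0,microbe,
5,1,0,0,1,plant,-45.742
5,1,0,0,1,microbe,
6,1,0,1,1,plant,-64.551
6,1,0,1,1,microbe,-28.054
7,1,0,1,0,plant,-63.956
7,1,0,1,0,microbe,
8,1,1,0,1,plant,-25.355
8,1,1,0,1,microbe,-14.909
9,0,1,1,1,plant,-61.141
9,0,1,1,1,microbe,
10,0,0,0,1,plant,-69.743
10,0,0,0,1,microbe,-21.361
11,0,0,1,1,plant,-28.668
11,0,0,1,1,microbe,
12,0,1,0,0,plant,-42.800
12,0,1,0,0,microbe,
13,1,1,1,1,plant,-92.927
13,1,1,1,1,microbe,-20.589
14,1,1,1,0,plant,
14,1,1,1,0,microbe,-18.142
15,1,0,0,0,plant,-81.088
15,1,0,0,0,microbe,-40.632
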