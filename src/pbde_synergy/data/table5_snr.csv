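group,factor,level1_mean,level2_mean,delta,rank
plant,A,-13.34,-0.73,12.61,3
microbe,A,-31.08,-16.88,14.2,3
plant,B,-8.98,-5.08,3.90,11
microbe,B,-32.04,-15.92,16.12,2
plant,C,-11.95,-2.11,9.83,5
microbe,C,-28.02,-19.94,8.08,8
plant,D,-11.67,-2.39,9.28,6
microbe,D,-33.35,-14.61,18.74,1
plant,E,-10.96,-3.10,7.86,9
microbe,E,-28.8,-19.17,9.63,7
plant,F,0.97,-15.03,16.00,2
microbe,F,-30.36,-17.61,12.75,5
plant,G,-1.99,-12.07,10.08,4
microbe,G,-27.77,-20.2,7.57,4
plant,H,-21.11,7.04,28.15,1
microbe,H,-29.6,-18.36,11.24,6
plant,I,-2.99,-11.07,8.08,8
microbe,I,-26.73,-21.23,5.49,10
plant,J,-2.73,-11.33,8.60,7
microbe,J,-30.47,-17.49,12.98,9
plant,K,-4.27,-9.79,5.52,10
microbe,K,-25.07,-22.9,2.17,11
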