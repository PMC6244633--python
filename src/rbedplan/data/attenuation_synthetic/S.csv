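energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,2.252251e+01,2.233364e+01
1.122018e-02,1.600008e+01,1.581246e+01
1.258925e-02,1.138220e+01,1.119598e+01
1.412538e-02,8.112615e+00,7.927934e+00
1.584893e-02,5.797508e+00,5.614522e+00
1.778279e-02,4.158078e+00,3.976955e+00
1.995262e-02,2.996946e+00,2.817866e+00
2.238721e-02,2.174376e+00,1.997530e+00
2.511886e-02,1.591439e+00,1.417030e+00
2.818383e-02,1.178096e+00,1.006338e+00
3.162278e-02,8.847619e-01,7.158763e-01
3.548134e-02,6.763298e-01,5.105467e-01
3.981072e-02,5.279453e-01,3.654998e-01
4.466836e-02,4.220119e-01,2.631420e-01
5.011872e-02,3.460720e-01,1.910157e-01
5.623413e-02,2.913072e-01,1.402988e-01
6.309573e-02,2.514763e-01,1.047426e-01
7.079458e-02,2.221632e-01,7.991981e-02
7.943282e-02,2.002456e-01,6.269241e-02
8.912509e-02,1.835174e-01,5.083478e-02
1.000000e-01,1.704224e-01,4.276726e-02
1.122018e-01,1.598652e-01,3.736763e-02
1.258925e-01,1.510773e-01,3.383769e-02
1.412538e-01,1.435218e-01,3.160906e-02
1.584893e-01,1.368261e-01,3.027651e-02
1.778279e-01,1.307337e-01,2.955086e-02
1.995262e-01,1.250700e-01,2.922567e-02
2.238721e-01,1.197177e-01,2.915361e-02
2.511886e-01,1.145995e-01,2.922966e-02
2.818383e-01,1.096653e-01,2.937920e-02
3.162278e-01,1.048837e-01,2.954942e-02
3.548134e-01,1.002354e-01,2.970316e-02
3.981072e-01,9.570889e-02,2.981451e-02
4.466836e-01,9.129769e-02,2.986565e-02
5.011872e-01,8.699825e-02,2.984456e-02
5.623413e-01,8.280872e-02,2.974350e-02
6.309573e-01,7.872830e-02,2.955789e-02
7.079458e-01,7.475677e-02,2.928557e-02
7.943282e-01,7.089435e-02,2.892640e-02
8.912509e-01,6.714162e-02,2.848187e-02
1.000000e+00,6.349949e-02,2.795495e-02
1.122018e+00,5.997345e-02,2.735025e-02
1.258925e+00,5.659495e-02,2.668010e-02
1.412538e+00,5.339358e-02,2.596756e-02
1.584893e+00,5.038586e-02,2.523865e-02
1.778279e+00,4.757920e-02,2.451729e-02
1.995262e+00,4.497483e-02,2.382311e-02
2.238721e+00,4.256990e-02,2.317103e-02
2.511886e+00,4.035890e-02,2.257150e-02
2.818383e+00,3.833470e-02,2.203127e-02
3.162278e+00,3.648927e-02,2.155407e-02
3.548134e+00,3.481406e-02,2.114139e-02
3.981072e+00,3.330039e-02,2.079309e-02
4.466836e+00,3.193959e-02,2.050788e-02
5.011872e+00,3.072315e-02,2.028372e-02
5.623413e+00,2.964278e-02,2.011810e-02
6.309573e+00,2.869045e-02,2.000827e-02
7.079458e+00,2.785842e-02,1.995136e-02
7.943282e+00,2.713926e-02,1.994446e-02
8.912509e+00,2.652585e-02,1.998472e-02
1.000000e+01,2.601135e-02,2.006939e-02
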