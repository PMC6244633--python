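energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,5.952754e+00,5.771671e+00
1.122018e-02,4.267300e+00,4.087427e+00
1.258925e-02,3.073761e+00,2.895225e+00
1.412538e-02,2.228436e+00,2.051376e+00
1.584893e-02,1.629591e+00,1.454156e+00
1.778279e-02,1.205200e+00,1.031551e+00
1.995262e-02,9.042709e-01,7.325808e-01
2.238721e-02,6.907005e-01,5.211527e-01
2.511886e-02,5.389272e-01,3.717160e-01
2.818383e-02,4.308520e-01,2.661818e-01
3.162278e-02,3.536598e-01,1.917438e-01
3.548134e-02,2.982763e-01,1.393347e-01
3.981072e-02,2.582760e-01,1.025343e-01
4.466836e-02,2.291092e-01,7.679561e-02
5.011872e-02,2.075550e-01,5.889754e-02
5.623413e-02,1.913337e-01,4.655706e-02
6.309573e-02,1.788332e-01,3.815490e-02
7.079458e-02,1.689147e-01,3.254133e-02
7.943282e-02,1.607754e-01,2.889872e-02
8.912509e-02,1.538515e-01,2.664442e-02
1.000000e-01,1.477491e-01,2.536204e-02
1.122018e-01,1.421954e-01,2.475306e-02
1.258925e-01,1.370039e-01,2.460256e-02
1.412538e-01,1.320496e-01,2.475523e-02
1.584893e-01,1.272509e-01,2.509840e-02
1.778279e-01,1.225573e-01,2.555008e-02
1.995262e-01,1.179396e-01,2.605059e-02
2.238721e-01,1.133833e-01,2.655655e-02
2.511886e-01,1.088834e-01,2.703658e-02
2.818383e-01,1.044411e-01,2.746816e-02
3.162278e-01,1.000608e-01,2.783539e-02
3.548134e-01,9.574874e-02,2.812723e-02
3.981072e-01,9.151130e-02,2.833625e-02
4.466836e-01,8.735454e-02,2.845767e-02
5.011872e-01,8.328377e-02,2.848870e-02
5.623413e-01,7.930343e-02,2.842810e-02
6.309573e-01,7.541708e-02,2.827583e-02
7.079458e-01,7.162763e-02,2.803294e-02
7.943282e-01,6.793748e-02,2.770146e-02
8.912509e-01,6.434874e-02,2.728439e-02
1.000000e+00,6.086336e-02,2.678566e-02
1.122018e+00,5.748611e-02,2.621037e-02
1.258925e+00,5.423869e-02,2.556881e-02
1.412538e+00,5.114150e-02,2.487847e-02
1.584893e+00,4.820622e-02,2.415894e-02
1.778279e+00,4.543844e-02,2.342852e-02
1.995262e+00,4.283961e-02,2.270278e-02
2.238721e+00,4.040833e-02,2.199417e-02
2.511886e+00,3.814138e-02,2.131222e-02
2.818383e+00,3.603428e-02,2.066391e-02
3.162278e+00,3.408179e-02,2.005417e-02
3.548134e+00,3.227820e-02,1.948627e-02
3.981072e+00,3.061750e-02,1.896224e-02
4.466836e+00,2.909355e-02,1.848315e-02
5.011872e+00,2.770011e-02,1.804937e-02
5.623413e+00,2.643097e-02,1.766074e-02
6.309573e+00,2.527994e-02,1.731669e-02
7.079458e+00,2.424089e-02,1.701639e-02
7.943282e+00,2.330780e-02,1.675876e-02
8.912509e+00,2.247476e-02,1.654258e-02
1.000000e+01,2.173601e-02,1.636649e-02
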