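energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,2.170400e+00,1.981157e+00
1.122018e-02,1.591991e+00,1.404012e+00
1.258925e-02,1.182164e+00,9.955824e-01
1.412538e-02,8.916482e-01,7.066088e-01
1.584893e-02,6.855598e-01,5.022189e-01
1.778279e-02,5.391999e-01,3.577257e-01
1.995262e-02,4.350798e-01,2.556524e-01
2.238721e-02,3.608156e-01,1.836271e-01
2.511886e-02,3.076375e-01,1.328909e-01
2.818383e-02,2.693341e-01,9.724305e-02
3.162278e-02,2.415059e-01,7.229305e-02
3.548134e-02,2.210362e-01,5.493186e-02
3.981072e-02,2.057174e-01,4.295709e-02
4.466836e-02,1.939855e-01,3.480777e-02
5.011872e-02,1.847333e-01,2.937659e-02
5.623413e-02,1.771779e-01,2.587688e-02
6.309573e-02,1.707666e-01,2.374857e-02
7.079458e-02,1.651107e-01,2.259162e-02
7.943282e-02,1.599387e-01,2.211901e-02
8.912509e-02,1.550632e-01,2.212351e-02
1.000000e-01,1.503569e-01,2.245438e-02
1.122018e-01,1.457359e-01,2.300095e-02
1.258925e-01,1.411480e-01,2.368117e-02
1.412538e-01,1.365632e-01,2.443362e-02
1.584893e-01,1.319680e-01,2.521199e-02
1.778279e-01,1.273601e-01,2.598119e-02
1.995262e-01,1.227447e-01,2.671463e-02
2.238721e-01,1.181319e-01,2.739232e-02
2.511886e-01,1.135347e-01,2.799941e-02
2.818383e-01,1.089668e-01,2.852509e-02
3.162278e-01,1.044420e-01,2.896171e-02
3.548134e-01,9.997301e-02,2.930411e-02
3.981072e-01,9.557108e-02,2.954903e-02
4.466836e-01,9.124575e-02,2.969467e-02
5.011872e-01,8.700481e-02,2.974038e-02
5.623413e-01,8.285448e-02,2.968644e-02
6.309573e-01,7.879965e-02,2.953396e-02
7.079458e-01,7.484413e-02,2.928483e-02
7.943282e-01,7.099102e-02,2.894175e-02
8.912509e-01,6.724291e-02,2.850825e-02
1.000000e+00,6.360213e-02,2.798872e-02
1.122018e+00,6.007306e-02,2.738861e-02
1.258925e+00,5.667288e-02,2.671753e-02
1.412538e+00,5.341776e-02,2.599072e-02
1.584893e+00,5.031719e-02,2.522519e-02
1.778279e+00,4.737602e-02,2.443709e-02
1.995262e+00,4.459584e-02,2.364058e-02
2.238721e+00,4.197604e-02,2.284751e-02
2.511886e+00,3.951447e-02,2.206747e-02
2.818383e+00,3.720794e-02,2.130811e-02
3.162278e+00,3.505251e-02,2.057535e-02
3.548134e+00,3.304374e-02,1.987380e-02
3.981072e+00,3.117681e-02,1.920691e-02
4.466836e+00,2.944663e-02,1.857726e-02
5.011872e+00,2.784792e-02,1.798667e-02
5.623413e+00,2.637525e-02,1.743638e-02
6.309573e+00,2.502310e-02,1.692711e-02
7.079458e+00,2.378587e-02,1.645919e-02
7.943282e+00,2.265797e-02,1.603255e-02
8.912509e+00,2.163381e-02,1.564687e-02
1.000000e+01,2.070783e-02,1.530153e-02
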