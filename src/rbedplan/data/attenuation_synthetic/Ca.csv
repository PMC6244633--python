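energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,4.895001e+01,4.876115e+01
1.122018e-02,3.470931e+01,3.452170e+01
1.258925e-02,2.462732e+01,2.444111e+01
1.412538e-02,1.748944e+01,1.730477e+01
1.584893e-02,1.243578e+01,1.225281e+01
1.778279e-02,8.857614e+00,8.676504e+00
1.995262e-02,6.323959e+00,6.144892e+00
2.238721e-02,4.529716e+00,4.352884e+00
2.511886e-02,3.258888e+00,3.084493e+00
2.818383e-02,2.358556e+00,2.186811e+00
3.162278e-02,1.720460e+00,1.551587e+00
3.548134e-02,1.267955e+00,1.102184e+00
3.981072e-02,9.467801e-01,7.843467e-01
4.466836e-02,7.185206e-01,5.596626e-01
5.011872e-02,5.559805e-01,4.009359e-01
5.623413e-02,4.399076e-01,2.889105e-01
6.309573e-02,3.566739e-01,2.099512e-01
7.079458e-02,2.966342e-01,1.544014e-01
7.943282e-02,2.529638e-01,1.154209e-01
8.912509e-02,2.208359e-01,8.816318e-02
1.000000e-01,1.968388e-01,6.919324e-02
1.122018e-01,1.785637e-01,5.607526e-02
1.258925e-01,1.643120e-01,4.708113e-02
1.412538e-01,1.528885e-01,4.098412e-02
1.584893e-01,1.434546e-01,3.691296e-02
1.778279e-01,1.354238e-01,3.424850e-02
1.995262e-01,1.283879e-01,3.255072e-02
2.238721e-01,1.220643e-01,3.150693e-02
2.511886e-01,1.162585e-01,3.089504e-02
2.818383e-01,1.108377e-01,3.055755e-02
3.162278e-01,1.057117e-01,3.038297e-02
3.548134e-01,1.008196e-01,3.029261e-02
3.981072e-01,9.612060e-02,3.023116e-02
4.466836e-01,9.158740e-02,3.015995e-02
5.011872e-01,8.720167e-02,3.005226e-02
5.623413e-01,8.295115e-02,2.988990e-02
6.309573e-01,7.882762e-02,2.966089e-02
7.079458e-01,7.482566e-02,2.935787e-02
7.943282e-01,7.094178e-02,2.897697e-02
8.912509e-01,6.717393e-02,2.851707e-02
1.000000e+00,6.352117e-02,2.797928e-02
1.122018e+00,5.998875e-02,2.736701e-02
1.258925e+00,5.661469e-02,2.669337e-02
1.412538e+00,5.343491e-02,2.598493e-02
1.584893e+00,5.046915e-02,2.527197e-02
1.778279e+00,4.772592e-02,2.458207e-02
1.995262e+00,4.520611e-02,2.393749e-02
2.238721e+00,4.290565e-02,2.335458e-02
2.511886e+00,4.081729e-02,2.284417e-02
2.818383e+00,3.893188e-02,2.241250e-02
3.162278e+00,3.723926e-02,2.206218e-02
3.548134e+00,3.572886e-02,2.179314e-02
3.981072e+00,3.439000e-02,2.160339e-02
4.466836e+00,3.321223e-02,2.148972e-02
5.011872e+00,3.218541e-02,2.144815e-02
5.623413e+00,3.129979e-02,2.147431e-02
6.309573e+00,3.054610e-02,2.156367e-02
7.079458e+00,2.991550e-02,2.171178e-02
7.943282e+00,2.939965e-02,2.191430e-02
8.912509e+00,2.899064e-02,2.216714e-02
1.000000e+01,2.868100e-02,2.246645e-02
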