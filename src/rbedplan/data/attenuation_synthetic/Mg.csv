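energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,8.261531e+00,8.074674e+00
1.122018e-02,5.903482e+00,5.717873e+00
1.258925e-02,4.233770e+00,4.049542e+00
1.412538e-02,3.051330e+00,2.868624e+00
1.584893e-02,2.213812e+00,2.032784e+00
1.778279e-02,1.620441e+00,1.441255e+00
1.995262e-02,1.199867e+00,1.022702e+00
2.238721e-02,9.015775e-01,7.266234e-01
2.511886e-02,6.898093e-01,5.172664e-01
2.818383e-02,5.392410e-01,3.693201e-01
3.162278e-02,4.319443e-01,2.648654e-01
3.548134e-02,3.552250e-01,1.912153e-01
3.981072e-02,3.000948e-01,1.393871e-01
4.466836e-02,2.601899e-01,1.030195e-01
5.011872e-02,2.310047e-01,7.760711e-02
5.623413e-02,2.093505e-01,5.995741e-02
6.309573e-02,1.929713e-01,4.780727e-02
7.079458e-02,1.802728e-01,3.955101e-02
7.943282e-02,1.701298e-01,3.404809e-02
8.912509e-02,1.617504e-01,3.048713e-02
1.000000e-01,1.545793e-01,2.828971e-02
1.122018e-01,1.482297e-01,2.704246e-02
1.258925e-01,1.424345e-01,2.644905e-02
1.412538e-01,1.370120e-01,2.629643e-02
1.584893e-01,1.318408e-01,2.643095e-02
1.778279e-01,1.268420e-01,2.674159e-02
1.995262e-01,1.219671e-01,2.714802e-02
2.238721e-01,1.171875e-01,2.759220e-02
2.511886e-01,1.124890e-01,2.803237e-02
2.818383e-01,1.078660e-01,2.843867e-02
3.162278e-01,1.033184e-01,2.878997e-02
3.548134e-01,9.884927e-02,2.907155e-02
3.981072e-01,9.446285e-02,2.927337e-02
4.466836e-01,9.016374e-02,2.938886e-02
5.011872e-01,8.595623e-02,2.941394e-02
5.623413e-01,8.184405e-02,2.934648e-02
6.309573e-01,7.783030e-02,2.918588e-02
7.079458e-01,7.391755e-02,2.893278e-02
7.943282e-01,7.010799e-02,2.858899e-02
8.912509e-01,6.640358e-02,2.815739e-02
1.000000e+00,6.280619e-02,2.764188e-02
1.122018e+00,5.932090e-02,2.704765e-02
1.258925e+00,5.597189e-02,2.638567e-02
1.412538e+00,5.278187e-02,2.567497e-02
1.584893e+00,4.976377e-02,2.493688e-02
1.778279e+00,4.692370e-02,2.419127e-02
1.995262e+00,4.426309e-02,2.345487e-02
2.238721e+00,4.178025e-02,2.274092e-02
2.511886e+00,3.947142e-02,2.205937e-02
2.818383e+00,3.733150e-02,2.141732e-02
3.162278e+00,3.535458e-02,2.081957e-02
3.548134e+00,3.353425e-02,2.026912e-02
3.981072e+00,3.186384e-02,1.976762e-02
4.466836e+00,3.033656e-02,1.931570e-02
5.011872e+00,2.894559e-02,1.891326e-02
5.623413e+00,2.768414e-02,1.855967e-02
6.309573e+00,2.654552e-02,1.825393e-02
7.079458e+00,2.552315e-02,1.799477e-02
7.943282e+00,2.461059e-02,1.778073e-02
8.912509e+00,2.380154e-02,1.761024e-02
1.000000e+01,2.308989e-02,1.748163e-02
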