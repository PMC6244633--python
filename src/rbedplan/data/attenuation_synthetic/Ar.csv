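energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,3.062076e+01,3.045023e+01
1.122018e-02,2.172782e+01,2.155843e+01
1.258925e-02,1.543179e+01,1.526365e+01
1.412538e-02,1.097420e+01,1.080745e+01
1.584893e-02,7.818085e+00,7.652874e+00
1.778279e-02,5.583315e+00,5.419786e+00
1.995262e-02,4.000764e+00,3.839079e+00
2.238721e-02,2.879905e+00,2.720238e+00
2.511886e-02,2.085855e+00,1.928388e+00
2.818383e-02,1.523119e+00,1.368045e+00
3.162278e-02,1.124091e+00,9.716105e-01
3.548134e-02,8.409080e-01,6.912288e-01
3.981072e-02,6.396843e-01,4.930185e-01
4.466836e-02,4.964296e-01,3.529921e-01
5.011872e-02,3.941600e-01,2.541657e-01
5.623413e-02,3.208527e-01,1.845131e-01
6.309573e-02,2.679977e-01,1.355175e-01
7.079458e-02,2.295726e-01,1.011465e-01
7.943282e-02,2.013174e-01,7.712592e-02
8.912509e-02,1.802202e-01,6.042618e-02
1.000000e-01,1.641538e-01,4.889896e-02
1.122018e-01,1.516181e-01,4.101975e-02
1.258925e-01,1.415571e-01,3.570598e-02
1.412538e-01,1.332299e-01,3.218823e-02
1.584893e-01,1.261187e-01,2.991923e-02
1.778279e-01,1.198635e-01,2.850948e-02
1.995262e-01,1.142158e-01,2.768167e-02
2.238721e-01,1.090052e-01,2.723841e-02
2.511886e-01,1.041165e-01,2.703933e-02
2.818383e-01,9.947205e-02,2.698481e-02
3.162278e-01,9.502073e-02,2.700430e-02
3.548134e-01,9.072893e-02,2.704811e-02
3.981072e-01,8.657486e-02,2.708139e-02
4.466836e-01,8.254456e-02,2.707995e-02
5.011872e-01,7.862905e-02,2.702720e-02
5.623413e-01,7.482263e-02,2.691210e-02
6.309573e-01,7.112168e-02,2.672762e-02
7.079458e-01,6.752397e-02,2.646980e-02
7.943282e-01,6.402828e-02,2.613705e-02
8.912509e-01,6.063410e-02,2.572971e-02
1.000000e+00,5.734151e-02,2.524972e-02
1.122018e+00,5.415547e-02,2.470081e-02
1.258925e+00,5.110738e-02,2.409450e-02
1.412538e+00,4.822687e-02,2.345324e-02
1.584893e+00,4.553033e-02,2.280248e-02
1.778279e+00,4.302497e-02,2.216549e-02
1.995262e+00,4.071176e-02,2.156120e-02
2.238721e+00,3.858758e-02,2.100373e-02
2.511886e+00,3.664669e-02,2.050269e-02
2.818383e+00,3.488174e-02,2.006396e-02
3.162278e+00,3.328452e-02,1.969040e-02
3.548134e+00,3.184640e-02,1.938266e-02
3.981072e+00,3.055865e-02,1.913977e-02
4.466836e+00,2.941263e-02,1.895971e-02
5.011872e+00,2.839992e-02,1.883975e-02
5.623413e+00,2.751239e-02,1.877680e-02
6.309573e+00,2.674221e-02,1.876757e-02
7.079458e+00,2.608192e-02,1.880874e-02
7.943282e+00,2.552439e-02,1.889706e-02
8.912509e+00,2.506282e-02,1.902939e-02
1.000000e+01,2.469077e-02,1.920274e-02
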