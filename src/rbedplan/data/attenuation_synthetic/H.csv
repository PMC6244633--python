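energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,3.853484e-01,9.888967e-03
1.122018e-02,3.828487e-01,9.897818e-03
1.258925e-02,3.803955e-01,1.021731e-02
1.412538e-02,3.779042e-01,1.078560e-02
1.584893e-02,3.753093e-01,1.156038e-02
1.778279e-02,3.725584e-01,1.251301e-02
1.995262e-02,3.696086e-01,1.362423e-02
2.238721e-02,3.664237e-01,1.488106e-02
2.511886e-02,3.629722e-01,1.627450e-02
2.818383e-02,3.592270e-01,1.779781e-02
3.162278e-02,3.551639e-01,1.944518e-02
3.548134e-02,3.507623e-01,2.121070e-02
3.981072e-02,3.460044e-01,2.308756e-02
4.466836e-02,3.408764e-01,2.506738e-02
5.011872e-02,3.353680e-01,2.713975e-02
5.623413e-02,3.294737e-01,2.929190e-02
6.309573e-02,3.231927e-01,3.150851e-02
7.079458e-02,3.165299e-01,3.377172e-02
7.943282e-02,3.094960e-01,3.606129e-02
8.912509e-02,3.021077e-01,3.835492e-02
1.000000e-01,2.943877e-01,4.062882e-02
1.122018e-01,2.863648e-01,4.285828e-02
1.258925e-01,2.780729e-01,4.501848e-02
1.412538e-01,2.695507e-01,4.708525e-02
1.584893e-01,2.608402e-01,4.903583e-02
1.778279e-01,2.519856e-01,5.084954e-02
1.995262e-01,2.430322e-01,5.250831e-02
2.238721e-01,2.340246e-01,5.399701e-02
2.511886e-01,2.250057e-01,5.530353e-02
2.818383e-01,2.160153e-01,5.641872e-02
3.162278e-01,2.070892e-01,5.733613e-02
3.548134e-01,1.982590e-01,5.805167e-02
3.981072e-01,1.895512e-01,5.856323e-02
4.466836e-01,1.809878e-01,5.887033e-02
5.011872e-01,1.725867e-01,5.897386e-02
5.623413e-01,1.643615e-01,5.887594e-02
6.309573e-01,1.563231e-01,5.857986e-02
7.079458e-01,1.484799e-01,5.809015e-02
7.943282e-01,1.408386e-01,5.741270e-02
8.912509e-01,1.334046e-01,5.655491e-02
1.000000e+00,1.261829e-01,5.552577e-02
1.122018e+00,1.191786e-01,5.433598e-02
1.258925e+00,1.123999e-01,5.299867e-02
1.412538e+00,1.058545e-01,5.152969e-02
1.584893e+00,9.954867e-02,4.994649e-02
1.778279e+00,9.348698e-02,4.826716e-02
1.995262e+00,8.767302e-02,4.650994e-02
2.238721e+00,8.210926e-02,4.469276e-02
2.511886e+00,7.679714e-02,4.283300e-02
2.818383e+00,7.173706e-02,4.094723e-02
3.162278e+00,6.692834e-02,3.905101e-02
3.548134e+00,6.236921e-02,3.715873e-02
3.981072e+00,5.805685e-02,3.528353e-02
4.466836e+00,5.398736e-02,3.343716e-02
5.011872e+00,5.015587e-02,3.162996e-02
5.623413e+00,4.655662e-02,2.987086e-02
6.309573e+00,4.318299e-02,2.816736e-02
7.079458e+00,4.002766e-02,2.652564e-02
7.943282e+00,3.708272e-02,2.495054e-02
8.912509e+00,3.433976e-02,2.344573e-02
1.000000e+01,3.179001e-02,2.201377e-02
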