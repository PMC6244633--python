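energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,9.144691e-01,7.254109e-01
1.122018e-02,7.028054e-01,5.150103e-01
1.258925e-02,5.526148e-01,3.662158e-01
1.412538e-02,4.459080e-01,2.610497e-01
1.584893e-02,3.699468e-01,1.867853e-01
1.778279e-02,3.157103e-01,1.344136e-01
1.995262e-02,2.768091e-01,9.755727e-02
2.238721e-02,2.487169e-01,7.170170e-02
2.511886e-02,2.282266e-01,5.365099e-02
2.818383e-02,2.130651e-01,4.114237e-02
3.162278e-02,2.016207e-01,3.257344e-02
3.548134e-02,1.927507e-01,2.680885e-02
3.981072e-02,1.856446e-01,2.304354e-02
4.466836e-02,1.797277e-01,2.070576e-02
5.011872e-02,1.745933e-01,1.938850e-02
5.623413e-02,1.699539e-01,1.880088e-02
6.309573e-02,1.656080e-01,1.873384e-02
7.079458e-02,1.614154e-01,1.903581e-02
7.943282e-02,1.572806e-01,1.959569e-02
8.912509e-02,1.531405e-01,2.033081e-02
1.000000e-01,1.489560e-01,2.117860e-02
1.122018e-01,1.447057e-01,2.209082e-02
1.258925e-01,1.403815e-01,2.302961e-02
1.412538e-01,1.359848e-01,2.396485e-02
1.584893e-01,1.315240e-01,2.487239e-02
1.778279e-01,1.270125e-01,2.573281e-02
1.995262e-01,1.224667e-01,2.653065e-02
2.238721e-01,1.179046e-01,2.725378e-02
2.511886e-01,1.133445e-01,2.789291e-02
2.818383e-01,1.088042e-01,2.844117e-02
3.162278e-01,1.043002e-01,2.889373e-02
3.548134e-01,9.984714e-02,2.924737e-02
3.981072e-01,9.545772e-02,2.950025e-02
4.466836e-01,9.114242e-02,2.965156e-02
5.011872e-01,8.690973e-02,2.970133e-02
5.623413e-01,8.276638e-02,2.965035e-02
6.309573e-01,7.871757e-02,2.950008e-02
7.079458e-01,7.476738e-02,2.925265e-02
7.943282e-01,7.091907e-02,2.891094e-02
8.912509e-01,6.717536e-02,2.847859e-02
1.000000e+00,6.353866e-02,2.796008e-02
1.122018e+00,6.001286e-02,2.736088e-02
1.258925e+00,5.661144e-02,2.668975e-02
1.412538e+00,5.334706e-02,2.595987e-02
1.584893e+00,5.022740e-02,2.518590e-02
1.778279e+00,4.725658e-02,2.438197e-02
1.995262e+00,4.443627e-02,2.356082e-02
2.238721e+00,4.176640e-02,2.273349e-02
2.511886e+00,3.924563e-02,2.190932e-02
2.818383e+00,3.687175e-02,2.109616e-02
3.162278e+00,3.464185e-02,2.030048e-02
3.548134e+00,3.255251e-02,1.952763e-02
3.981072e+00,3.059988e-02,1.878197e-02
4.466836e+00,2.877979e-02,1.806702e-02
5.011872e+00,2.708774e-02,1.738559e-02
5.623413e+00,2.551905e-02,1.673983e-02
6.309573e+00,2.406881e-02,1.613135e-02
7.079458e+00,2.273199e-02,1.556125e-02
7.943282e+00,2.150345e-02,1.503021e-02
8.912509e+00,2.037800e-02,1.453849e-02
1.000000e+01,1.935041e-02,1.408605e-02
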