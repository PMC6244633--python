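energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,1.747405e+01,1.729076e+01
1.122018e-02,1.242439e+01,1.224234e+01
1.258925e-02,8.849182e+00,8.668479e+00
1.412538e-02,6.317757e+00,6.138547e+00
1.584893e-02,4.525239e+00,4.347674e+00
1.778279e-02,3.255788e+00,3.080031e+00
1.995262e-02,2.356596e+00,2.182821e+00
2.238721e-02,1.719481e+00,1.547875e+00
2.511886e-02,1.267854e+00,1.098613e+00
2.818383e-02,9.474916e-01,7.808225e-01
3.162278e-02,7.200031e-01,5.561215e-01
3.548134e-02,5.582090e-01,3.973380e-01
3.981072e-02,4.428662e-01,2.852339e-01
4.466836e-02,3.603507e-01,2.061881e-01
5.011872e-02,3.010174e-01,1.505554e-01
5.623413e-02,2.580390e-01,1.115049e-01
6.309573e-02,2.265835e-01,8.419748e-02
7.079458e-02,2.032329e-01,6.520410e-02
7.943282e-02,1.855709e-01,5.209335e-02
8.912509e-02,1.718913e-01,4.314004e-02
1.000000e-01,1.609917e-01,3.711895e-02
1.122018e-01,1.520269e-01,3.315883e-02
1.258925e-01,1.444052e-01,3.063933e-02
1.412538e-01,1.377148e-01,2.911801e-02
1.584893e-01,1.316715e-01,2.827894e-02
1.778279e-01,1.260810e-01,2.789619e-02
1.995262e-01,1.208127e-01,2.780817e-02
2.238721e-01,1.157801e-01,2.789933e-02
2.511886e-01,1.109275e-01,2.808716e-02
2.818383e-01,1.062203e-01,2.831301e-02
3.162278e-01,1.016375e-01,2.853534e-02
3.548134e-01,9.716737e-02,2.872498e-02
3.981072e-01,9.280363e-02,2.886168e-02
4.466836e-01,8.854341e-02,2.893158e-02
5.011872e-01,8.438572e-02,2.892548e-02
5.623413e-01,8.033049e-02,2.883758e-02
6.309573e-01,7.637816e-02,2.866465e-02
7.079458e-01,7.252940e-02,2.840550e-02
7.943282e-01,6.878503e-02,2.806058e-02
8.912509e-01,6.514605e-02,2.763178e-02
1.000000e+00,6.161364e-02,2.712227e-02
1.122018e+00,5.819309e-02,2.653675e-02
1.258925e+00,5.491326e-02,2.588689e-02
1.412538e+00,5.180127e-02,2.519418e-02
1.584893e+00,4.887233e-02,2.448281e-02
1.778279e+00,4.613334e-02,2.377505e-02
1.995262e+00,4.358557e-02,2.308932e-02
2.238721e+00,4.122652e-02,2.243971e-02
2.511886e+00,3.905126e-02,2.183628e-02
2.818383e+00,3.705337e-02,2.128569e-02
3.162278e+00,3.522555e-02,2.079183e-02
3.548134e+00,3.356000e-02,2.035652e-02
3.981072e+00,3.204878e-02,1.998006e-02
4.466836e+00,3.068391e-02,1.966168e-02
5.011872e+00,2.945753e-02,1.939986e-02
5.623413e+00,2.836194e-02,1.919262e-02
6.309573e+00,2.738965e-02,1.903772e-02
7.079458e+00,2.653342e-02,1.893275e-02
7.943282e+00,2.578625e-02,1.887524e-02
8.912509e+00,2.514143e-02,1.886274e-02
1.000000e+01,2.459248e-02,1.889282e-02
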