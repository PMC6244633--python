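energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,2.671371e+01,2.653222e+01
1.122018e-02,1.896505e+01,1.878477e+01
1.258925e-02,1.347909e+01,1.330015e+01
1.412538e-02,9.594962e+00,9.417503e+00
1.584893e-02,6.844809e+00,6.668979e+00
1.778279e-02,4.897408e+00,4.723368e+00
1.995262e-02,3.518270e+00,3.346192e+00
2.238721e-02,2.541384e+00,2.371453e+00
2.511886e-02,1.849223e+00,1.681635e+00
2.818383e-02,1.358582e+00,1.193540e+00
3.162278e-02,1.010552e+00,8.482707e-01
3.548134e-02,7.634285e-01,6.041282e-01
3.981072e-02,5.876849e-01,4.315917e-01
4.466836e-02,4.624173e-01,3.097599e-01
5.011872e-02,3.728268e-01,2.238339e-01
5.623413e-02,3.084374e-01,1.633340e-01
6.309573e-02,2.618341e-01,1.208384e-01
7.079458e-02,2.277703e-01,9.108922e-02
7.943282e-02,2.025349e-01,7.036068e-02
8.912509e-02,1.835053e-01,5.601119e-02
1.000000e-01,1.688301e-01,4.616680e-02
1.122018e-01,1.572044e-01,3.949704e-02
1.258925e-01,1.477115e-01,3.505647e-02
1.412538e-01,1.397091e-01,3.217260e-02
1.584893e-01,1.327496e-01,3.036658e-02
1.778279e-01,1.265234e-01,2.929723e-02
1.995262e-01,1.208177e-01,2.872134e-02
2.238721e-01,1.154883e-01,2.846561e-02
2.511886e-01,1.104382e-01,2.840667e-02
2.818383e-01,1.056035e-01,2.845690e-02
3.162278e-01,1.009427e-01,2.855430e-02
3.548134e-01,9.642930e-02,2.865518e-02
3.981072e-01,9.204663e-02,2.872902e-02
4.466836e-01,8.778446e-02,2.875468e-02
5.011872e-01,8.363652e-02,2.871780e-02
5.623413e-01,7.959906e-02,2.860892e-02
6.309573e-01,7.566987e-02,2.842223e-02
7.079458e-01,7.184774e-02,2.815467e-02
7.943282e-01,6.813219e-02,2.780537e-02
8.912509e-01,6.452326e-02,2.737527e-02
1.000000e+00,6.102145e-02,2.686686e-02
1.122018e+00,5.763208e-02,2.628435e-02
1.258925e+00,5.438696e-02,2.563982e-02
1.412538e+00,5.131609e-02,2.495630e-02
1.584893e+00,4.843615e-02,2.425985e-02
1.778279e+00,4.575452e-02,2.357433e-02
1.995262e+00,4.327233e-02,2.291927e-02
2.238721e+00,4.098654e-02,2.230934e-02
2.511886e+00,3.889146e-02,2.175469e-02
2.818383e+00,3.697975e-02,2.126168e-02
3.162278e+00,3.524317e-02,2.083363e-02
3.548134e+00,3.367305e-02,2.047160e-02
3.981072e+00,3.226055e-02,2.017501e-02
4.466836e+00,3.099691e-02,1.994216e-02
5.011872e+00,2.987358e-02,1.977063e-02
5.623413e+00,2.888223e-02,1.965757e-02
6.309573e+00,2.801484e-02,1.959989e-02
7.079458e+00,2.726373e-02,1.959445e-02
7.943282e+00,2.662153e-02,1.963814e-02
8.912509e+00,2.608119e-02,1.972790e-02
1.000000e+01,2.563602e-02,1.986082e-02
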