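energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,1.431290e+00,1.242153e+00
1.122018e-02,1.068710e+00,8.808366e-01
1.258925e-02,8.116782e-01,6.252017e-01
1.412538e-02,6.293337e-01,4.443984e-01
1.584893e-02,4.998249e-01,3.165870e-01
1.778279e-02,4.076793e-01,2.263071e-01
1.995262e-02,3.419404e-01,1.626139e-01
2.238721e-02,2.948483e-01,1.177594e-01
2.511886e-02,2.609068e-01,8.625851e-02
2.818383e-02,2.362223e-01,6.422805e-02
3.162278e-02,2.180360e-01,4.891828e-02
3.548134e-02,2.043927e-01,3.838168e-02
3.981072e-02,1.939069e-01,3.123817e-02
4.466836e-02,1.855971e-01,2.650894e-02
5.011872e-02,1.787682e-01,2.349880e-02
5.623413e-02,1.729289e-01,2.171287e-02
6.309573e-02,1.677330e-01,2.079762e-02
7.079458e-02,1.629382e-01,2.049927e-02
7.943282e-02,1.583765e-01,2.063429e-02
8.912509e-02,1.539337e-01,2.106877e-02
1.000000e-01,1.495344e-01,2.170386e-02
1.122018e-01,1.451316e-01,2.246563e-02
1.258925e-01,1.406988e-01,2.329803e-02
1.412538e-01,1.362246e-01,2.415807e-02
1.584893e-01,1.317085e-01,2.501247e-02
1.778279e-01,1.271573e-01,2.583536e-02
1.995262e-01,1.225828e-01,2.660672e-02
2.238721e-01,1.179997e-01,2.731116e-02
2.511886e-01,1.134243e-01,2.793711e-02
2.818383e-01,1.088726e-01,2.847609e-02
3.162278e-01,1.043599e-01,2.892209e-02
3.548134e-01,9.990028e-02,2.927112e-02
3.981072e-01,9.550566e-02,2.952072e-02
4.466836e-01,9.118617e-02,2.966970e-02
5.011872e-01,8.695003e-02,2.971780e-02
5.623413e-01,8.280375e-02,2.966560e-02
6.309573e-01,7.875241e-02,2.951442e-02
7.079458e-01,7.479997e-02,2.926629e-02
7.943282e-01,7.094964e-02,2.892401e-02
8.912509e-01,6.720406e-02,2.849118e-02
1.000000e+00,6.356564e-02,2.797224e-02
1.122018e+00,6.003849e-02,2.737267e-02
1.258925e+00,5.663796e-02,2.670163e-02
1.412538e+00,5.337846e-02,2.597336e-02
1.584893e+00,5.026858e-02,2.520367e-02
1.778279e+00,4.731280e-02,2.440772e-02
1.995262e+00,4.451276e-02,2.359895e-02
2.238721e+00,4.186811e-02,2.278880e-02
2.511886e+00,3.937711e-02,2.198675e-02
2.818383e+00,3.703706e-02,2.120053e-02
3.162278e+00,3.484454e-02,2.043635e-02
3.548134e+00,3.279561e-02,1.969919e-02
3.981072e+00,3.088595e-02,1.899295e-02
4.466836e+00,2.911092e-02,1.832068e-02
5.011872e+00,2.746564e-02,1.768469e-02
5.623413e+00,2.594505e-02,1.708669e-02
6.309573e+00,2.454393e-02,1.652783e-02
7.079458e+00,2.325698e-02,1.600883e-02
7.943282e+00,2.207882e-02,1.553000e-02
8.912509e+00,2.100406e-02,1.509131e-02
1.000000e+01,2.002733e-02,1.469242e-02
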