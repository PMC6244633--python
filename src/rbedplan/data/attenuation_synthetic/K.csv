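energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,3.986541e+01,3.968149e+01
1.122018e-02,2.827645e+01,2.809376e+01
1.258925e-02,2.007176e+01,1.989043e+01
1.412538e-02,1.426292e+01,1.408309e+01
1.584893e-02,1.015017e+01,9.971985e+00
1.778279e-02,7.238112e+00,7.061745e+00
1.995262e-02,5.176045e+00,5.001667e+00
2.238721e-02,3.715676e+00,3.543474e+00
2.511886e-02,2.681227e+00,2.511399e+00
2.818383e-02,1.948256e+00,1.781009e+00
3.162278e-02,1.428661e+00,1.264211e+00
3.548134e-02,1.060069e+00,8.986394e-01
3.981072e-02,7.983213e-01,6.401418e-01
4.466836e-02,6.121562e-01,4.574584e-01
5.011872e-02,4.794415e-01,3.284571e-01
5.623413e-02,3.845095e-01,2.374667e-01
6.309573e-02,3.162702e-01,1.733899e-01
7.079458e-02,2.668749e-01,1.283669e-01
7.943282e-02,2.307707e-01,9.682979e-02
8.912509e-02,2.040310e-01,7.483276e-02
1.000000e-01,1.838813e-01,5.957851e-02
1.122018e-01,1.683636e-01,4.908287e-02
1.258925e-01,1.560984e-01,4.193755e-02
1.412538e-01,1.461161e-01,3.714233e-02
1.584893e-01,1.377378e-01,3.398633e-02
1.778279e-01,1.304898e-01,3.196406e-02
1.995262e-01,1.240433e-01,3.071598e-02
2.238721e-01,1.181722e-01,2.998641e-02
2.511886e-01,1.127216e-01,2.959364e-02
2.818383e-01,1.075865e-01,2.940878e-02
3.162278e-01,1.026965e-01,2.934056e-02
3.548134e-01,9.800462e-02,2.932463e-02
3.981072e-01,9.347972e-02,2.931580e-02
4.466836e-01,8.910136e-02,2.928258e-02
5.011872e-01,8.485605e-02,2.920327e-02
5.623413e-01,8.073494e-02,2.906326e-02
6.309573e-01,7.673222e-02,2.885307e-02
7.079458e-01,7.284413e-02,2.856705e-02
7.943282e-01,6.906838e-02,2.820255e-02
8.912509e-01,6.540376e-02,2.775924e-02
1.000000e+00,6.184987e-02,2.723876e-02
1.122018e+00,5.841198e-02,2.664477e-02
1.258925e+00,5.512554e-02,2.598992e-02
1.412538e+00,5.202403e-02,2.529925e-02
1.584893e+00,4.912592e-02,2.460123e-02
1.778279e+00,4.643924e-02,2.392185e-02
1.995262e+00,4.396496e-02,2.328216e-02
2.238721e+00,4.169940e-02,2.269774e-02
2.511886e+00,3.963594e-02,2.217905e-02
2.818383e+00,3.776618e-02,2.173229e-02
3.162278e+00,3.608074e-02,2.136028e-02
3.548134e+00,3.456981e-02,2.106333e-02
3.981072e+00,3.322350e-02,2.083997e-02
4.466836e+00,3.203204e-02,2.068753e-02
5.011872e+00,3.098597e-02,2.060260e-02
5.623413e+00,3.007616e-02,2.058139e-02
6.309573e+00,2.929386e-02,2.061992e-02
7.079458e+00,2.863076e-02,2.071424e-02
7.943282e+00,2.807894e-02,2.086048e-02
8.912509e+00,2.763088e-02,2.105494e-02
1.000000e+01,2.727949e-02,2.129416e-02
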