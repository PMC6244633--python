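energy_MeV,mu_over_rho,mu_en_over_rho
1.000000e-02,6.001547e+02,6.000029e+02
1.122018e-02,4.249215e+02,4.247707e+02
1.258925e-02,3.008656e+02,3.007159e+02
1.412538e-02,2.130404e+02,2.128920e+02
1.584893e-02,1.508646e+02,1.507176e+02
1.778279e-02,1.068472e+02,1.067016e+02
1.995262e-02,7.568482e+01,7.554089e+01
2.238721e-02,5.362310e+01,5.348097e+01
2.511886e-02,3.800412e+01,3.786395e+01
2.818383e-02,2.694620e+01,2.680816e+01
3.162278e-02,1.911722e+01,1.898149e+01
3.548134e-02,1.357411e+01,1.344088e+01
3.981072e-02,9.649228e+00,9.518676e+00
4.466836e-02,6.869912e+00,6.742233e+00
5.011872e-02,4.901547e+00,4.776933e+00
5.623413e-02,3.507245e+00,3.385884e+00
6.309573e-02,2.519303e+00,2.401377e+00
7.079458e-02,1.818997e+00,1.704680e+00
7.943282e-02,1.322282e+00,1.211734e+00
8.912509e-02,6.902318e+00,6.795685e+00
1.000000e-01,4.919017e+00,4.816425e+00
1.122018e-01,3.513914e+00,3.415466e+00
1.258925e-01,2.518121e+00,2.423899e+00
1.412538e-01,1.812081e+00,1.722140e+00
1.584893e-01,1.311161e+00,1.225530e+00
1.778279e-01,9.554494e-01,8.741319e-01
1.995262e-01,7.025398e-01,6.255127e-01
2.238721e-01,5.224144e-01,4.496309e-01
2.511886e-01,3.938273e-01,3.252182e-01
2.818383e-01,3.017411e-01,2.372177e-01
3.162278e-01,2.355136e-01,1.749698e-01
3.548134e-01,1.876129e-01,1.309284e-01
3.981072e-01,1.527087e-01,9.975145e-02
4.466836e-01,1.270286e-01,7.765762e-02
5.011872e-01,1.079030e-01,6.197035e-02
5.623413e-01,9.344226e-02,5.079539e-02
6.309573e-01,8.230918e-02,4.279245e-02
7.079458e-01,7.355735e-02,3.701356e-02
7.943282e-01,6.651703e-02,3.278870e-02
8.912509e-01,6.071447e-02,2.964483e-02
1.000000e+00,5.581462e-02,2.724857e-02
1.122018e+00,5.159788e-02,2.536720e-02
1.258925e+00,4.801615e-02,2.386424e-02
1.412538e+00,4.506257e-02,2.269188e-02
1.584893e+00,4.271283e-02,2.184630e-02
1.778279e+00,4.093117e-02,2.133791e-02
1.995262e+00,3.967512e-02,2.117627e-02
2.238721e+00,3.889905e-02,2.136371e-02
2.511886e+00,3.855668e-02,2.189365e-02
2.818383e+00,3.860282e-02,2.275132e-02
3.162278e+00,3.899451e-02,2.391549e-02
3.548134e+00,3.969171e-02,2.536054e-02
3.981072e+00,4.065769e-02,2.705832e-02
4.466836e+00,4.185910e-02,2.897979e-02
5.011872e+00,4.326603e-02,3.109624e-02
5.623413e+00,4.485177e-02,3.338020e-02
6.309573e+00,4.659267e-02,3.580606e-02
7.079458e+00,4.846791e-02,3.835041e-02
7.943282e+00,5.045920e-02,4.099225e-02
8.912509e+00,5.255054e-02,4.371298e-02
1.000000e+01,5.472800e-02,4.649637e-02
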