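energy_MeV,relative_fluence
0.25,9.831832e-02
0.50,1.090486e-01
0.75,1.062632e-01
1.00,9.820360e-02
1.25,8.815742e-02
1.50,7.769846e-02
1.75,6.761771e-02
2.00,5.830138e-02
2.25,4.991366e-02
2.50,4.249446e-02
2.75,3.601480e-02
3.00,3.040940e-02
3.25,2.559604e-02
3.50,2.148710e-02
3.75,1.799630e-02
4.00,1.504244e-02
4.25,1.255128e-02
4.50,1.045637e-02
4.75,8.698999e-03
5.00,7.227958e-03
5.25,5.998916e-03
5.50,4.973777e-03
5.75,4.119985e-03
6.00,3.409849e-03
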