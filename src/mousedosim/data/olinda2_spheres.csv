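# Reference sphere-model dose factors for Tb-152 uniformly distributed in
# unit-density spheres (published OLINDA/EXM 2.0 sphere-model values),
# used for tumor-dose interpolation and as the reference column of the
# sphere-model comparison. DF units: mGy/(MBq h) for a TIAC of 1 h.
mass_g,diameter_cm,df_mgy_per_mbqh
0.1,0.58,6.78e2
0.5,0.98,1.84e2
1.0,1.24,1.11e2
2.0,1.56,6.09e1
4.0,1.97,3.30e1
6.0,2.25,2.30e1
8.0,2.48,1.78e1
10.0,2.67,1.46e1
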