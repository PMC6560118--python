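# Electron CSDA range in liquid water (continuous-slowing-down approximation),
# ESTAR-style values; log-log interpolated between rows.
energy_mev,csda_g_cm2
0.01,2.515e-4
0.02,8.566e-4
0.03,1.756e-3
0.05,4.320e-3
0.07,7.718e-3
0.10,1.431e-2
0.15,2.817e-2
0.20,4.487e-2
0.30,8.421e-2
0.40,1.288e-1
0.50,1.766e-1
0.70,2.752e-1
1.00,4.367e-1
1.50,7.075e-1
2.00,9.785e-1
3.00,1.514e0
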