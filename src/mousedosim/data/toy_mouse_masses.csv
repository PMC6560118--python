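# Reference organ masses (g) of the synthetic toy 25 g mouse-like phantom.
compartment,mass_g
heart,0.23
lungs,0.08
liver,1.73
kidneys,0.30
small_intestine,1.74
large_intestine,0.58
rest_of_body,20.30
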