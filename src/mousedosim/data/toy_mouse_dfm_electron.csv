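# Electron (non-penetrating) component of the synthetic toy DF matrix.
# Self-dose only: charged-particle cross-fire is negligible at organ
# separations much larger than the electron range.
target,heart,lungs,liver,kidneys,small_intestine,large_intestine,rest_of_body
heart,395.0,0.0,0.0,0.0,0.0,0.0,0.0
lungs,0.0,1154.0,0.0,0.0,0.0,0.0,0.0
liver,0.0,0.0,64.7,0.0,0.0,0.0,0.0
kidneys,0.0,0.0,0.0,312.0,0.0,0.0,0.0
small_intestine,0.0,0.0,0.0,0.0,64.5,0.0,0.0
large_intestine,0.0,0.0,0.0,0.0,0.0,174.0,0.0
rest_of_body,0.0,0.0,0.0,0.0,0.0,0.0,6.55
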