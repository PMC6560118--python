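# Photon (penetrating) component of the synthetic toy DF matrix.
# Complement of the electron component: total = electron + photon exactly.
target,heart,lungs,liver,kidneys,small_intestine,large_intestine,rest_of_body
heart,21.0,4.0,3.0,0.8,0.5,0.4,1.2
lungs,4.0,40.0,2.5,0.7,0.4,0.3,1.2
liver,3.0,2.5,5.6,2.2,1.8,1.2,1.0
kidneys,0.8,0.7,2.2,18.0,2.0,1.5,1.1
small_intestine,0.5,0.4,1.8,2.0,5.6,3.5,1.0
large_intestine,0.4,0.3,1.2,1.5,3.5,10.0,1.0
rest_of_body,0.9,0.8,0.9,0.9,0.9,0.9,1.71
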