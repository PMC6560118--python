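# Default tissue mass densities (g/mL) for VOI mass computation,
# ICRP-110-derived soft-tissue values; every entry overridable in config.
compartment,density_g_ml
heart,1.05
lungs,0.26
liver,1.06
kidneys,1.05
intestines,1.03
small_intestine,1.03
large_intestine,1.03
spleen,1.06
tumor,1.00
carcass,1.00
whole_body,1.00
soft_tissue,1.00
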