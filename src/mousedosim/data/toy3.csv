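# Toy three-line nuclide for tests and worked examples (synthetic).
# name = Toy-3
# half_life_h = 10.0
kind,energy_mev,yield,endpoint_mev
photon,0.100,1.000,
electron_mono,0.500,0.500,
beta_plus,0.300,0.200,1.000
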