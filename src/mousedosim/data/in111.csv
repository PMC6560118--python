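# In-111 emission line list (synthetic compilation).
# Assembled from evaluated-nuclear-data summaries of the In-111 -> Cd-111
# electron-capture decay; NOT an export of any licensed database.
# Only the half-life enters the cross-isotope extrapolation; the line
# inventory is provided for completeness (gammas 171/245 keV, Cd K x-rays,
# conversion and Auger electrons).
# name = In-111
# half_life_h = 67.32
kind,energy_mev,yield,endpoint_mev
photon,0.17128,0.907,
photon,0.24535,0.941,
photon,0.02317,0.680,
photon,0.02610,0.150,
electron_mono,0.14454,0.0830,
electron_mono,0.16729,0.0100,
electron_mono,0.21861,0.0500,
electron_mono,0.24170,0.0100,
electron_mono,0.01910,0.1550,
electron_mono,0.00260,1.0200,
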