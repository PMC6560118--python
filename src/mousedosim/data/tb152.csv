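# Tb-152 emission line list (synthetic compilation).
# Assembled from evaluated-nuclear-data summaries of the Tb-152 -> Gd-152
# electron-capture / beta+ decay; NOT an export of any licensed database.
# The beta+ branch matches the published summary values: mean energy
# 1.140 MeV, 20.3% intensity, endpoint 2.97 MeV. Annihilation photons
# (2 x 0.511 MeV per beta+) are listed explicitly.
# Gamma intensities for weak high-energy transitions are approximate.
# name = Tb-152
# half_life_h = 17.5
kind,energy_mev,yield,endpoint_mev
beta_plus,1.140,0.203,2.970
photon,0.0429,0.470,
photon,0.0487,0.120,
photon,0.27113,0.0953,
photon,0.34428,0.635,
photon,0.41112,0.0302,
photon,0.511,0.406,
photon,0.58629,0.0921,
photon,0.76490,0.0192,
photon,0.97410,0.0102,
photon,1.10920,0.0068,
photon,1.29914,0.0039,
photon,1.48820,0.0061,
photon,1.62190,0.0075,
electron_mono,0.29380,0.0160,
electron_mono,0.33630,0.0030,
electron_mono,0.22090,0.0020,
electron_mono,0.03500,0.0400,
electron_mono,0.00500,0.6000,
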