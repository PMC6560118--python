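"""Unit conventions and the single set of conversion constants.

Conventions used throughout the package:

* time: hours
* activity: MBq; activity concentration: kBq/mL
* energy: MeV; emission yields: per decay
* mass: g; length: mm for images/masks, cm for the ellipsoid model
* dose: mGy; dose factors: mGy/(MBq h); TIACs: MBq h/MBq
"""

#: joule per MeV
J_PER_MEV = 1.602e-13

#: number of decays corresponding to 1 MBq sustained for 1 hour
DECAYS_PER_MBQ_H = 3.6e9

#: milligray per gray
MGY_PER_GY = 1.0e3


def absorbed_energy_to_df(energy_mev_per_decay: float, mass_g: float) -> float:
    """Convert absorbed energy per decay (MeV) in a mass (g) to a dose factor.

    Returns mGy/(MBq h): E[MeV] * J/MeV * decays/(MBq h) / m[kg] * mGy/Gy.
    """
    mass_kg = mass_g * 1e-3
    return energy_mev_per_decay * J_PER_MEV * DECAYS_PER_MBQ_H / mass_kg * MGY_PER_GY
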