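from dataclasses import replace

import numpy as np
import pytest

import mousedosim as md


@pytest.fixture(scope="session")
def tb():
    return md.tb152()


@pytest.fixture(scope="session")
def indium():
    return md.in111()


@pytest.fixture(scope="session")
def toy():
    return md.toy_nuclide()


@pytest.fixture(scope="session")
def scenario():
    return md.scenario_default()


@pytest.fixture(scope="session")
def noiseless_scenario(scenario):
    return replace(
        scenario,
        cohort=replace(scenario.cohort, noise_cv=0.0),
        phantom=replace(scenario.phantom, noise_cv=0.0, counts_scale=None),
    )


@pytest.fixture(scope="session")
def noiseless_study(noiseless_scenario):
    """One noiseless blurred animal of the default digital mouse."""
    sc = noiseless_scenario
    return md.simulate_imaging_series(sc.kinetics, sc.phantom, sc.imaging_nuclide)


@pytest.fixture(scope="session")
def sharp_study(noiseless_scenario):
    """One noiseless animal without any PSF blur (ideal scanner)."""
    sc = noiseless_scenario
    phantom = replace(sc.phantom, psf_sigma_mm=0.0)
    return md.simulate_imaging_series(sc.kinetics, phantom, sc.imaging_nuclide)


@pytest.fixture(scope="session")
def phantom_meas(scenario):
    return md.phantom_measurement(scenario.phantom)
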