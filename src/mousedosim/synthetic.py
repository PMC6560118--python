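"""Synthetic study generator: biodistribution cohorts and longitudinal
digital-mouse images with known ground truth.

The generator emulates the two experimental arms the pipeline consumes:

* **Dissection cohorts** — groups of animals sacrificed at fixed times;
  each organ's activity fraction follows a mono-exponential biological
  clearance multiplied by the physical decay of the measured label, with
  multiplicative lognormal inter-animal variability (unit mean).

* **Imaging series** — a digital mouse made of ellipsoidal organs inside an
  ellipsoidal body, painted with activity concentrations, blurred with a
  Gaussian PSF (spill-out/spill-in), and degraded with Poisson counting
  noise.  VOI masks are the *unblurred* organ supports, so partial-volume
  bias is present in the measurement exactly as it is in a real scanner.

Ground-truth TIACs are analytic: A0_bio / (lambda_bio + lambda_phys).
Every stochastic element draws from an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .calibration import PhantomMeasurement, VOIMask, VoxelImage
from .errors import InvalidArgumentError, SpecificationError
from .nuclides import Radionuclide, decay_fraction, in111, tb152

ORGAN_COMPARTMENTS = ("heart", "lungs", "liver", "kidneys", "intestines", "tumor")


@dataclass(frozen=True)
class CompartmentKinetics:
    """Mono-exponential biological kinetics of one compartment:
    fraction of injected activity A0_bio clearing at lambda_bio (per hour)."""

    name: str
    a0: float
    lam_bio: float

    def __post_init__(self):
        if self.a0 < 0:
            raise InvalidArgumentError(f"{self.name}: A0_bio must be >= 0")
        if self.lam_bio < 0:
            raise InvalidArgumentError(f"{self.name}: lambda_bio must be >= 0")

    def na(self, t: float, nuclide: Radionuclide) -> float:
        """Noise-free nA at time t for the given physical label."""
        return self.a0 * math.exp(-self.lam_bio * t) * decay_fraction(nuclide, t)

    def true_tiac(self, nuclide: Radionuclide) -> float:
        return self.a0 / (self.lam_bio + nuclide.decay_constant)


def _check_kinetics(kinetics: Sequence[CompartmentKinetics]):
    total = sum(k.a0 for k in kinetics)
    if total > 1.0 + 1e-9:
        raise SpecificationError(
            f"compartment A0_bio fractions sum to {total:.3f} > 1"
        )


@dataclass(frozen=True)
class CohortSpec:
    """Dissection-study design: sacrifice schedule, group sizes, noise, label."""

    schedule: tuple = (4.0, 24.0, 48.0, 96.0)
    n_per_time: tuple = (3, 5, 4, 3)
    noise_cv: float = 0.10
    nuclide: Radionuclide = field(default_factory=in111)
    injected_mbq: float = 0.15
    seed: int = 42

    def __post_init__(self):
        if len(self.schedule) != len(self.n_per_time):
            raise InvalidArgumentError("schedule and n_per_time lengths differ")
        if any(n < 1 for n in self.n_per_time):
            raise InvalidArgumentError("each time point needs >= 1 animal")
        if any(b <= a for a, b in zip(self.schedule, self.schedule[1:])) is True:
            raise InvalidArgumentError("schedule must be increasing")
        if self.noise_cv < 0:
            raise InvalidArgumentError("noise_cv must be >= 0")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_biodistribution(
    kinetics: Sequence[CompartmentKinetics],
    spec: CohortSpec,
):
    """Simulate a dissection cohort.

    Returns ``(table, truth)``: a DataFrame with columns
    ``animal_id, compartment, time_h, nA`` (one row per compartment per
    animal, plus a ``whole_body`` row summing that animal's compartments),
    and the ground-truth TIAC per compartment (including ``whole_body``)
    for the cohort's nuclide.
    """
    _check_kinetics(kinetics)
    measured = [k for k in kinetics if k.name != "excreta"]  # excreta leaves the body
    rng = np.random.default_rng(spec.seed)
    rows = []
    animal = 0
    for t, n in zip(spec.schedule, spec.n_per_time):
        for _ in range(n):
            animal += 1
            noise = _lognormal_factors(rng, spec.noise_cv, len(measured))
            total = 0.0
            for k, f in zip(measured, noise):
                na = k.na(t, spec.nuclide) * f
                total += na
                rows.append(
                    {
                        "animal_id": f"m{animal:02d}",
                        "compartment": k.name,
                        "time_h": t,
                        "nA": na,
                    }
                )
            rows.append(
                {
                    "animal_id": f"m{animal:02d}",
                    "compartment": "whole_body",
                    "time_h": t,
                    "nA": total,
                }
            )
    truth = {k.name: k.true_tiac(spec.nuclide) for k in measured}
    truth["whole_body"] = sum(truth.values())
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# digital mouse imaging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrganShape:
    """Ellipsoidal organ: center offset from body center and semi-axes, mm."""

    center_mm: tuple
    semi_axes_mm: tuple


# The liver dome is deliberately broad and flat so that the heart and lungs
# sit just above it across an extended interface, as they do across the
# diaphragm in vivo; this is what makes hepatic spill-in to thoracic VOIs a
# property of the geometry rather than of a single tangent point.
_DEFAULT_ORGANS = {
    "liver": OrganShape((0.0, 0.0, 7.5), (9.0, 8.0, 4.5)),
    "heart": OrganShape((0.0, 3.5, 14.7), (4.0, 3.5, 3.0)),
    "lungs": OrganShape((0.0, -4.0, 14.9), (5.0, 3.5, 3.3)),
    "kidneys": OrganShape((5.0, -4.0, -2.0), (3.0, 2.5, 4.0)),
    "intestines": OrganShape((2.0, 3.0, -19.0), (7.0, 6.0, 8.0)),
    "tumor": OrganShape((-6.0, -4.0, -14.0), (5.0, 4.5, 5.0)),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Digital-mouse imaging design.

    The body and organs are ellipsoids (sufficient to exercise VOI
    quantification, spill-out and mass computation); the whole-body VOI is
    the body support dilated by ``whole_body_margin_mm`` so PSF tails stay
    inside it.  ``counts_scale`` (expected counts per kBq/mL per voxel)
    controls Poisson noise; ``None`` disables it.  ``gain`` converts
    concentration to raw scanner signal; the matching phantom measurement
    comes from :func:`phantom_measurement`.
    """

    shape: tuple = (76, 72, 152)
    voxel_size_mm: float = 0.5
    body_semi_axes_mm: tuple = (14.0, 13.0, 32.0)
    organs: Mapping[str, OrganShape] = field(
        default_factory=lambda: dict(_DEFAULT_ORGANS)
    )
    psf_sigma_mm: float = 0.6
    counts_scale: Optional[float] = 2.0
    gain: float = 1.0 / 205.0
    times: tuple = (4.0, 24.0, 48.0)
    injected_mbq: float = 7.0
    n_animals: int = 4
    noise_cv: float = 0.10
    whole_body_margin_mm: float = 3.0
    seed: int = 42

    def __post_init__(self):
        if self.psf_sigma_mm < 0:
            raise InvalidArgumentError("psf_sigma_mm must be >= 0")
        if self.voxel_size_mm <= 0:
            raise InvalidArgumentError("voxel size must be > 0")


def _voxel_centers(spec: PhantomSpec):
    """Voxel-center coordinates (mm) relative to the image center."""
    axes = []
    for n in spec.shape:
        axes.append((np.arange(n) + 0.5 - n / 2.0) * spec.voxel_size_mm)
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_mask(coords, center, semi_axes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return (
        ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    ) <= 1.0


def build_masks(spec: PhantomSpec) -> dict:
    """Organ, body, carcass and whole-body masks on the voxel grid.

    Raises :class:`SpecificationError` if organ supports overlap or poke
    outside the body.
    """
    coords = _voxel_centers(spec)
    body = _ellipsoid_mask(coords, (0.0, 0.0, 0.0), spec.body_semi_axes_mm)
    masks = {}
    occupied = np.zeros(spec.shape, dtype=bool)
    for name, shape in spec.organs.items():
        m = _ellipsoid_mask(coords, shape.center_mm, shape.semi_axes_mm)
        if (m & occupied).any():
            raise SpecificationError(f"organ {name!r} overlaps another organ")
        if (m & ~body).any():
            raise SpecificationError(f"organ {name!r} extends outside the body")
        occupied |= m
        masks[name] = m
    masks["carcass"] = body & ~occupied
    masks["body"] = body
    wb_axes = tuple(s + spec.whole_body_margin_mm for s in spec.body_semi_axes_mm)
    masks["whole_body"] = _ellipsoid_mask(coords, (0.0, 0.0, 0.0), wb_axes)
    return masks


@dataclass
class ImagingStudy:
    """One simulated animal: uncalibrated images, VOI masks, ground truth."""

    images: list
    masks: dict
    truth: dict
    spec: PhantomSpec
    nuclide: Radionuclide


def simulate_imaging_series(
    kinetics: Sequence[CompartmentKinetics],
    phantom: PhantomSpec,
    nuclide: Radionuclide,
    seed: Optional[int] = None,
) -> ImagingStudy:
    """Simulate one animal's longitudinal scans.

    Painting: each compartment's activity (nA x injected) is spread
    uniformly over its support; the carcass holds every kinetic compartment
    without an organ shape (minus any ``excreta`` compartment, which leaves
    the body).  The painted concentration map is blurred with the Gaussian
    PSF, Poisson noise is applied at ``counts_scale``, and the result is
    scaled by the camera gain into raw-signal images.
    """
    _check_kinetics(kinetics)
    rng = np.random.default_rng(phantom.seed if seed is None else seed)
    masks = build_masks(phantom)
    vox_ml = (phantom.voxel_size_mm / 10.0) ** 3
    volumes = {name: m.sum() * vox_ml for name, m in masks.items()}
    organ_kin = {k.name: k for k in kinetics if k.name in phantom.organs}
    carcass_kin = [
        k
        for k in kinetics
        if k.name not in phantom.organs and k.name != "excreta"
    ]
    images = []
    painted = {}  # time -> compartment -> painted activity (MBq)
    for t in phantom.times:
        conc = np.zeros(phantom.shape)
        painted_t = {}
        noise = _lognormal_factors(rng, phantom.noise_cv, len(organ_kin) + 1)
        for (name, k), f in zip(organ_kin.items(), noise[:-1]):
            act_mbq = k.na(t, nuclide) * phantom.injected_mbq * f
            painted_t[name] = act_mbq
            conc[masks[name]] = act_mbq * 1e3 / volumes[name]  # kBq/mL
        carcass_act = sum(k.na(t, nuclide) for k in carcass_kin)
        carcass_act *= phantom.injected_mbq * noise[-1]
        painted_t["carcass"] = carcass_act
        conc[masks["carcass"]] = carcass_act * 1e3 / volumes["carcass"]
        if phantom.psf_sigma_mm > 0:
            conc = gaussian_filter(
                conc, sigma=phantom.psf_sigma_mm / phantom.voxel_size_mm
            )
        if phantom.counts_scale is not None:
            counts = rng.poisson(np.maximum(conc, 0.0) * phantom.counts_scale)
            conc = counts / phantom.counts_scale
        images.append(
            VoxelImage(
                data=conc * phantom.gain,
                voxel_size_mm=phantom.voxel_size_mm,
                time_h=t,
                calibrated=False,
            )
        )
        painted[t] = painted_t
    voi_masks = {
        name: VOIMask(data=masks[name], label=name)
        for name in list(phantom.organs) + ["whole_body"]
    }
    truth = {
        "tiac": {k.name: k.true_tiac(nuclide) for k in kinetics},
        "painted_mbq": painted,
        "volumes_ml": volumes,
    }
    truth["tiac"]["whole_body"] = sum(
        k.true_tiac(nuclide) for k in kinetics if k.name != "excreta"
    )
    return ImagingStudy(
        images=images, masks=voi_masks, truth=truth, spec=phantom, nuclide=nuclide
    )


def phantom_measurement(
    spec: PhantomSpec, fill_activity_mbq: float = 8.2, fill_volume_ml: float = 20.0
) -> PhantomMeasurement:
    """Uniform-phantom measurement consistent with the camera gain."""
    a_c_bg = fill_activity_mbq / fill_volume_ml * 1e3  # kBq/mL
    return PhantomMeasurement(
        s_bg=a_c_bg * spec.gain,
        fill_activity_mbq=fill_activity_mbq,
        fill_volume_ml=fill_volume_ml,
    )


# ---------------------------------------------------------------------------
# the default scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    kinetics: tuple
    cohort: CohortSpec
    phantom: PhantomSpec
    imaging_nuclide: Radionuclide


def scenario_default() -> Scenario:
    """Liver-dominant antibody-like scenario.

    Rapid blood (heart) clearance, strong hepatic uptake with slow washout,
    tumor retention, and a carcass compartment; 7.5% of the injected
    activity is excreted (decays outside the whole-body masks).  The
    dissection cohort is labeled with In-111, imaging with Tb-152, sharing
    the same biology — the cross-isotope design the pipeline exists for.
    """
    # A0 fractions are sized for realistic %IA/g given the phantom organ
    # volumes: the liver concentration exceeds heart/lung concentrations
    # roughly tenfold, which is what drives hepatic spill-in to thoracic
    # VOIs once blood (heart) activity has cleared.
    kinetics = (
        CompartmentKinetics("heart", 0.005, 0.045),
        CompartmentKinetics("lungs", 0.008, 0.040),
        CompartmentKinetics("liver", 0.300, 0.008),
        CompartmentKinetics("kidneys", 0.025, 0.010),
        CompartmentKinetics("intestines", 0.080, 0.012),
        CompartmentKinetics("tumor", 0.055, 0.004),
        CompartmentKinetics("carcass", 0.440, 0.015),
        CompartmentKinetics("excreta", 0.080, 0.030),
    )
    return Scenario(
        kinetics=kinetics,
        cohort=CohortSpec(nuclide=in111(), seed=42),
        phantom=PhantomSpec(seed=42),
        imaging_nuclide=tb152(),
    )
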