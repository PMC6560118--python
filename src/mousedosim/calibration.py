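"""Phantom-based count-to-activity calibration and VOI quantification.

A uniformly filled image-quality phantom with known activity concentration
provides a single scaling factor converting scanner signal to kBq/mL; VOI
masks drawn on CT then yield organ activities (MBq), volumes and masses.
No partial-volume correction is applied anywhere: spill-out is a property
of the measurement that the synthetic-data generator reproduces so its bias
can be quantified, not silently corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from .errors import (
    CalibrationStateError,
    ConfigurationError,
    InvalidArgumentError,
)

#: relative tolerance for the phantom self-consistency check
_PHANTOM_RTOL = 0.005


@dataclass(frozen=True)
class PhantomMeasurement:
    """Uniform-phantom scan used to derive the calibration factor.

    ``s_bg`` is the mean image signal in the background region (signal units
    per mL-equivalent voxel value); ``a_c_bg`` the true activity
    concentration in kBq/mL.  If the fill activity (MBq) and volume (mL) are
    given, ``a_c_bg`` may be derived and is cross-checked to 0.5%.
    """

    s_bg: float
    a_c_bg: Optional[float] = None
    fill_activity_mbq: Optional[float] = None
    fill_volume_ml: Optional[float] = None

    def __post_init__(self):
        if not self.s_bg > 0:
            raise InvalidArgumentError("phantom background signal must be > 0")
        derived = None
        if self.fill_activity_mbq is not None and self.fill_volume_ml is not None:
            if self.fill_activity_mbq <= 0 or self.fill_volume_ml <= 0:
                raise InvalidArgumentError("phantom fill activity/volume must be > 0")
            derived = self.fill_activity_mbq / self.fill_volume_ml * 1e3  # kBq/mL
        if self.a_c_bg is None:
            if derived is None:
                raise InvalidArgumentError(
                    "either a_c_bg or (fill_activity_mbq, fill_volume_ml) required"
                )
            object.__setattr__(self, "a_c_bg", derived)
        else:
            if not self.a_c_bg > 0:
                raise InvalidArgumentError("phantom concentration must be > 0")
            if derived is not None and not math.isclose(
                self.a_c_bg, derived, rel_tol=_PHANTOM_RTOL
            ):
                raise InvalidArgumentError(
                    f"a_c_bg {self.a_c_bg:.4g} kBq/mL inconsistent with "
                    f"fill {derived:.4g} kBq/mL (beyond 0.5%)"
                )


@dataclass
class VoxelImage:
    """Isotropic 3-D image; voxel values are scanner signal until calibrated,
    activity concentration in kBq/mL afterwards."""

    data: np.ndarray
    voxel_size_mm: float
    time_h: float = 0.0
    calibrated: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise InvalidArgumentError("image must be a non-empty 3-D array")
        if not self.voxel_size_mm > 0:
            raise InvalidArgumentError("voxel size must be > 0")

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3  # mm -> cm; cm^3 == mL


@dataclass
class VOIMask:
    """Boolean mask congruent with its image, named after a compartment."""

    data: np.ndarray
    label: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise InvalidArgumentError("mask must be 3-D")
        if not self.data.any():
            raise InvalidArgumentError(f"mask {self.label!r} selects no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class OrganMassSet:
    """Per-compartment masses (g) and where they came from."""

    masses: Mapping[str, float]
    provenance: str = "segmented_ct"  # or "harvested", "phantom_default"

    def __post_init__(self):
        for organ, m in self.masses.items():
            if not m > 0:
                raise InvalidArgumentError(f"mass for {organ!r} must be > 0, got {m}")

    def __getitem__(self, organ: str) -> float:
        return self.masses[organ]


def scaling_factor(phantom: PhantomMeasurement) -> float:
    """Signal-to-concentration factor: (S_bg / A_c,bg)^-1 = A_c,bg / S_bg."""
    return phantom.a_c_bg / phantom.s_bg


def calibrate(image: VoxelImage, factor: float) -> VoxelImage:
    """Voxelwise multiplication by the calibration factor; flags the image."""
    if image.calibrated:
        raise CalibrationStateError("image is already calibrated")
    return VoxelImage(
        data=image.data * factor,
        voxel_size_mm=image.voxel_size_mm,
        time_h=image.time_h,
        calibrated=True,
    )


def voi_activity(image: VoxelImage, mask: VOIMask) -> float:
    """Total activity in the masked region, MBq."""
    if not image.calibrated:
        raise InvalidArgumentError("image must be calibrated before quantification")
    if image.data.shape != mask.data.shape:
        raise InvalidArgumentError(
            f"mask {mask.label!r} shape {mask.data.shape} does not match "
            f"image shape {image.data.shape}"
        )
    kbq = float(image.data[mask.data].sum()) * image.voxel_volume_ml
    return kbq * 1e-3


# ---------------------------------------------------------------------------
# masses and densities
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def default_densities() -> dict:
    """Packaged per-compartment densities (g/mL), ICRP-110-derived defaults."""
    path = Path(resources.files("mousedosim.data") / "densities.csv")
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("compartment"):
                continue
            name, val = line.split(",")
            table[name] = float(val)
    return table


def compartment_density(
    label: str, overrides: Optional[Mapping[str, float]] = None
) -> float:
    if overrides and label in overrides:
        return overrides[label]
    table = default_densities()
    if label not in table:
        raise ConfigurationError(
            f"no density configured for compartment {label!r}; "
            f"known: {sorted(table)} (or pass an override)"
        )
    return table[label]


def voi_mass(
    mask: VOIMask,
    voxel_size_mm: float,
    density: Optional[float] = None,
    density_overrides: Optional[Mapping[str, float]] = None,
) -> float:
    """Mass (g) of a VOI: voxel count x voxel volume x tissue density.

    With ``density=None`` the density is looked up from the compartment
    label (overrides first, packaged defaults second).
    """
    if density is None:
        density = compartment_density(mask.label, density_overrides)
    if not density > 0:
        raise InvalidArgumentError("density must be > 0")
    volume_ml = mask.n_voxels * (voxel_size_mm / 10.0) ** 3
    return volume_ml * density


# ---------------------------------------------------------------------------
# NIfTI I/O (CLI support)
# ---------------------------------------------------------------------------


def load_nifti(path, time_h: float = 0.0, calibrated: bool = False) -> VoxelImage:
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        raise InvalidArgumentError(f"anisotropic voxels {zooms} not supported")
    return VoxelImage(
        data=np.asanyarray(img.dataobj, dtype=float),
        voxel_size_mm=float(zooms[0]),
        time_h=time_h,
        calibrated=calibrated,
    )


def save_nifti(image: VoxelImage, path) -> None:
    import nibabel as nib

    affine = np.diag([image.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), str(path))


def load_mask_nifti(path, label: str) -> VOIMask:
    import nibabel as nib

    img = nib.load(str(path))
    return VOIMask(data=np.asanyarray(img.dataobj) > 0.5, label=label)


def save_mask_nifti(mask: VOIMask, voxel_size_mm: float, path) -> None:
    import nibabel as nib

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))
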