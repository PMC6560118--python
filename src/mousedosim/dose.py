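"""Organ absorbed doses from TIACs and a reference dose-factor matrix.

Implements the standard dose = sum_sources TIAC(source) x DF(target<-source)
bookkeeping, self-dose mass rescaling of a reference phantom matrix to the
subject's organ masses, the 75/25 small/large intestine partition, sphere
/ ellipsoid tumor doses, and the imaging-vs-biodistribution comparison
statistic RD%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, InvalidArgumentError

#: small/large intestine partition fractions of the merged intestine VOI
SMALL_INTESTINE_FRACTION = 0.75

#: acceptable tumor-mass domain of the sphere model, g
SPHERE_MASS_DOMAIN = (0.05, 20.0)


@dataclass
class DoseFactorMatrix:
    """Target x source dose-factor matrix of a reference phantom.

    ``entries`` is a DataFrame (rows = targets, columns = sources) in
    mGy/(MBq h); optional ``electron``/``photon`` component frames of the
    same shape allow component-wise self-dose mass rescaling; otherwise
    whole-DF 1/m scaling (the non-penetrating approximation) is used.
    """

    entries: pd.DataFrame
    reference_masses: dict
    phantom_name: str = "phantom"
    electron: Optional[pd.DataFrame] = None
    photon: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if (self.entries.values < 0).any():
            raise InvalidArgumentError("dose factors must be >= 0")
        for organ, m in self.reference_masses.items():
            if not m > 0:
                raise InvalidArgumentError(f"reference mass for {organ!r} must be > 0")
        if self.electron is not None and self.photon is not None:
            if not np.allclose(
                self.electron.values + self.photon.values, self.entries.values,
                rtol=1e-6, atol=1e-9,
            ):
                raise InvalidArgumentError(
                    "electron + photon components must sum to the total matrix"
                )

    @property
    def sources(self) -> list:
        return list(self.entries.columns)

    @property
    def targets(self) -> list:
        return list(self.entries.index)

    def df(self, target: str, source: str) -> float:
        return float(self.entries.at[target, source])

    @classmethod
    def from_csv(
        cls,
        path,
        masses_path=None,
        electron_path=None,
        photon_path=None,
        phantom_name: Optional[str] = None,
    ) -> "DoseFactorMatrix":
        entries = pd.read_csv(path, comment="#", index_col=0)
        entries.index.name = "target"
        masses = {}
        if masses_path is not None:
            mdf = pd.read_csv(masses_path, comment="#")
            masses = dict(zip(mdf["compartment"], mdf["mass_g"].astype(float)))
        electron = photon = None
        if electron_path is not None:
            electron = pd.read_csv(electron_path, comment="#", index_col=0)
        if photon_path is not None:
            photon = pd.read_csv(photon_path, comment="#", index_col=0)
        return cls(
            entries=entries,
            reference_masses=masses,
            phantom_name=phantom_name or Path(str(path)).stem,
            electron=electron,
            photon=photon,
        )


def _toy_data(name: str) -> Path:
    return Path(resources.files("mousedosim.data") / name)


@lru_cache(maxsize=1)
def toy_mouse_dfm() -> DoseFactorMatrix:
    """Packaged synthetic toy matrix for a 25 g mouse-like phantom (tests,
    examples; real rodent DF tables load through the same constructor)."""
    return DoseFactorMatrix.from_csv(
        _toy_data("toy_mouse_dfm.csv"),
        masses_path=_toy_data("toy_mouse_masses.csv"),
        electron_path=_toy_data("toy_mouse_dfm_electron.csv"),
        photon_path=_toy_data("toy_mouse_dfm_photon.csv"),
        phantom_name="toy-mouse-25g",
    )


def rescale_masses(
    dfm: DoseFactorMatrix, actual: Union[Mapping[str, float], "OrganMassSet"]
) -> DoseFactorMatrix:
    """Rescale self-dose entries from phantom masses to the subject's.

    Electron component scales with m_ref/m_actual (non-penetrating), photon
    component with (m_ref/m_actual)^(2/3); a matrix without the split scales
    the whole self-dose entry by m_ref/m_actual.  Cross terms are left
    untouched, and organs without a supplied mass keep reference values.
    """
    masses = getattr(actual, "masses", actual)
    valid = [o for o in dfm.sources if o in dfm.targets and o in dfm.reference_masses]
    unknown = [o for o in masses if o not in valid]
    if unknown:
        raise ConfigurationError(
            f"unknown organ(s) {unknown} for mass rescaling; valid: {valid}"
        )
    entries = dfm.entries.copy()
    electron = None if dfm.electron is None else dfm.electron.copy()
    photon = None if dfm.photon is None else dfm.photon.copy()
    for organ, m_actual in masses.items():
        if not m_actual > 0:
            raise InvalidArgumentError(f"actual mass for {organ!r} must be > 0")
        ratio = dfm.reference_masses[organ] / m_actual
        if electron is not None and photon is not None:
            e = electron.at[organ, organ] * ratio
            p = photon.at[organ, organ] * ratio ** (2.0 / 3.0)
            electron.at[organ, organ] = e
            photon.at[organ, organ] = p
            entries.at[organ, organ] = e + p
        else:
            entries.at[organ, organ] *= ratio
    return DoseFactorMatrix(
        entries=entries,
        reference_masses=dict(dfm.reference_masses),
        phantom_name=dfm.phantom_name,
        electron=electron,
        photon=photon,
    )


def partition_intestine(
    tiac_total: float, mass_total: float, si_fraction: float = SMALL_INTESTINE_FRACTION
) -> dict:
    """Split the merged intestine TIAC and mass 75% small / 25% large.

    Conservation is exact: the two parts sum to the totals.
    """
    if tiac_total < 0 or not mass_total > 0:
        raise InvalidArgumentError("intestine TIAC must be >= 0 and mass > 0")
    si_tiac = si_fraction * tiac_total
    si_mass = si_fraction * mass_total
    return {
        "small_intestine": {"tiac": si_tiac, "mass_g": si_mass},
        "large_intestine": {
            "tiac": tiac_total - si_tiac,
            "mass_g": mass_total - si_mass,
        },
    }


@dataclass
class DoseReport:
    """Per-target absorbed doses (mGy/MBq) with dispersions and provenance."""

    doses: dict
    sd: dict = field(default_factory=dict)
    method: str = "imaging"  # or "biodistribution"
    flags: list = field(default_factory=list)

    def __post_init__(self):
        for target, d in self.doses.items():
            if d < 0:
                raise InvalidArgumentError(f"dose for {target!r} must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target": t,
                "dose_mgy_per_mbq": d,
                "sd_mgy_per_mbq": self.sd.get(t, float("nan")),
                "method": self.method,
            }
            for t, d in self.doses.items()
        ]
        return pd.DataFrame(rows)


def organ_doses(
    tiacs: Mapping[str, float],
    dfm: DoseFactorMatrix,
    method: str = "imaging",
) -> DoseReport:
    """D(target) = sum_sources TIAC(source) x DF(target <- source).

    ``rest_of_body`` maps to the phantom's remainder column when present,
    else to ``total_body`` with a flag in the report.
    """
    flags = []
    columns = {}
    for source, value in tiacs.items():
        col = source
        if source not in dfm.sources:
            if source == "rest_of_body" and "total_body" in dfm.sources:
                col = "total_body"
                flags.append("rest_of_body approximated by total_body column")
            else:
                raise ConfigurationError(
                    f"source {source!r} not in DF matrix (has {dfm.sources})"
                )
        columns[col] = columns.get(col, 0.0) + float(value)
    doses = {}
    for target in dfm.targets:
        doses[target] = float(
            sum(dfm.df(target, col) * v for col, v in columns.items())
        )
    return DoseReport(doses=doses, method=method, flags=flags)


# ---------------------------------------------------------------------------
# tumor sphere model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SphereDFTable:
    """Mass -> DF table for unit-density spheres, log-log interpolated."""

    masses_g: np.ndarray
    dfs: np.ndarray
    name: str = "sphere-table"

    def __call__(self, mass_g: float) -> float:
        lo, hi = SPHERE_MASS_DOMAIN
        if not lo <= mass_g <= hi:
            raise DomainError(f"sphere mass {mass_g} g outside [{lo}, {hi}] g")
        return float(
            np.exp(
                np.interp(
                    np.log(mass_g), np.log(self.masses_g), np.log(self.dfs)
                )
            )
        )


@lru_cache(maxsize=1)
def olinda2_sphere_table() -> SphereDFTable:
    """Packaged reference sphere-model DF table for Tb-152 (unit density)."""
    df = pd.read_csv(_toy_data("olinda2_spheres.csv"), comment="#")
    return SphereDFTable(
        masses_g=df["mass_g"].to_numpy(float),
        dfs=df["df_mgy_per_mbqh"].to_numpy(float),
        name="olinda2-tb152-spheres",
    )


def tumor_dose(
    tiac: float,
    mass_g: float,
    sphere_dfs: Union[SphereDFTable, Callable[[float], float]],
) -> float:
    """Tumor absorbed dose, mGy/MBq: TIAC x DF(mass).

    ``sphere_dfs`` is either a tabulated sphere DF table (log-log
    interpolation) or any callable mass -> DF, e.g. the analytic ellipsoid
    model bound to a nuclide.
    """
    if tiac < 0:
        raise InvalidArgumentError("tumor TIAC must be >= 0")
    return tiac * float(sphere_dfs(mass_g))


def relative_difference(ad_im: float, ad_biod: float) -> float:
    """RD% = (AD_imaging - AD_biodistribution) / AD_biodistribution x 100."""
    if ad_biod == 0:
        raise InvalidArgumentError("biodistribution dose must be nonzero")
    return (ad_im - ad_biod) / ad_biod * 100.0
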