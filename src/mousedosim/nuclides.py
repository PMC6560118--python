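"""Radionuclide decay data: emission lines, decay arithmetic, and the
cross-isotope physical-decay scale factor used to extrapolate a
biodistribution measured with one isotope to the physics of another.

The scale factor assumes identical biology for the two labels and only
compensates for the differing physical half-lives:

    SF(t) = exp(-ln2 t / T_target) / exp(-ln2 t / T_source)

so that nA_target(t) = nA_source(t) * SF(t) for curves that embed physical
decay (i.e. are *not* decay-corrected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .errors import InvalidArgumentError, ParseError

LN2 = math.log(2.0)

PHOTON = "photon"
ELECTRON_MONO = "electron_mono"
BETA_PLUS = "beta_plus"
BETA_MINUS = "beta_minus"
KINDS = (PHOTON, ELECTRON_MONO, BETA_PLUS, BETA_MINUS)
BETA_KINDS = (BETA_PLUS, BETA_MINUS)


@dataclass(frozen=True)
class EmissionLine:
    """One emission per decay channel.

    Parameters
    ----------
    kind:
        One of ``photon``, ``electron_mono``, ``beta_plus``, ``beta_minus``.
    energy:
        Photon/monoenergetic-electron energy, or the *mean* energy of a beta
        spectrum, in MeV.
    yield_:
        Emissions per decay. Yields of a cascade may sum above 1.
    endpoint:
        Beta spectrum endpoint (MeV); required for beta kinds.
    spectrum:
        Optional binned beta spectrum ``(energies_mev, probabilities)`` for
        higher-fidelity absorbed-fraction integration; probabilities are
        normalized to 1 internally.
    """

    kind: str
    energy: float
    yield_: float
    endpoint: Optional[float] = None
    spectrum: Optional[tuple] = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InvalidArgumentError(f"unknown emission kind {self.kind!r}")
        if not self.energy > 0:
            raise InvalidArgumentError(f"line energy must be > 0, got {self.energy}")
        if not self.yield_ > 0:
            raise InvalidArgumentError(f"line yield must be > 0, got {self.yield_}")
        if self.kind in BETA_KINDS:
            if self.endpoint is None:
                raise InvalidArgumentError(f"{self.kind} line requires an endpoint energy")
            if self.endpoint < self.energy:
                raise InvalidArgumentError(
                    f"beta endpoint {self.endpoint} MeV below mean energy {self.energy} MeV"
                )

    @property
    def is_electron(self) -> bool:
        """True for any charged-particle (locally absorbed) emission."""
        return self.kind != PHOTON


@dataclass(frozen=True)
class Radionuclide:
    """A radionuclide: physical half-life (hours) plus its emission lines."""

    name: str
    half_life: float
    lines: tuple = ()

    def __post_init__(self):
        if not self.half_life > 0:
            raise InvalidArgumentError(f"half-life must be > 0, got {self.half_life}")
        object.__setattr__(self, "lines", tuple(self.lines))

    @property
    def decay_constant(self) -> float:
        """Physical decay constant, per hour."""
        return LN2 / self.half_life

    def lines_of_kind(self, *kinds: str) -> tuple:
        return tuple(l for l in self.lines if l.kind in kinds)


def decay_constant(half_life: float) -> float:
    """ln(2)/T_p, per hour, for a half-life in hours."""
    if not half_life > 0:
        raise InvalidArgumentError(f"half-life must be > 0, got {half_life}")
    return LN2 / half_life


def decay_fraction(nuclide: Union[Radionuclide, float], t: float) -> float:
    """Fraction of activity remaining after ``t`` hours of physical decay."""
    if t < 0:
        raise InvalidArgumentError(f"time must be >= 0, got {t}")
    half_life = nuclide.half_life if isinstance(nuclide, Radionuclide) else float(nuclide)
    return math.exp(-decay_constant(half_life) * t)


def physical_scale_factor(
    t_m: float, source: Radionuclide, target: Radionuclide
) -> float:
    """Physical-decay scale factor converting source-isotope nA to the target.

    ``SF(t) = decay_fraction(target, t) / decay_fraction(source, t)``;
    SF(0) = 1, and SF decreases with time when the target is shorter-lived.
    """
    if t_m < 0:
        raise InvalidArgumentError(f"time must be >= 0, got {t_m}")
    return decay_fraction(target, t_m) / decay_fraction(source, t_m)


# ---------------------------------------------------------------------------
# line-list files
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("kind", "energy_mev", "yield")


def load_line_list(
    path: Union[str, Path],
    name: Optional[str] = None,
    half_life: Optional[float] = None,
) -> Radionuclide:
    """Parse a comma-separated emission line list into a :class:`Radionuclide`.

    Dialect: ``#`` comment lines (``# key = value`` comments may carry
    ``name`` and ``half_life_h`` metadata), a header row
    ``kind,energy_mev,yield[,endpoint_mev]``, energies in MeV. A header
    mentioning keV is rejected outright so keV tables cannot slip through.
    """
    path = Path(path)
    meta: dict = {}
    header: Optional[list] = None
    lines: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            fields = [f.strip() for f in text.split(",")]
            if header is None:
                header = [f.lower() for f in fields]
                if any("kev" in h for h in header):
                    raise ParseError(
                        f"{path.name}: header {header} uses keV; energies must be in MeV"
                    )
                missing = [c for c in _REQUIRED_COLS if c not in header]
                if missing:
                    raise ParseError(f"{path.name}: missing required columns {missing}")
                continue
            row = dict(zip(header, fields))
            kind = row.get("kind", "")
            if kind not in KINDS:
                raise ParseError(f"{path.name} row {lineno}: unknown kind {kind!r}")
            try:
                energy = float(row["energy_mev"])
                yield_ = float(row["yield"])
                endpoint_txt = row.get("endpoint_mev", "")
                endpoint = float(endpoint_txt) if endpoint_txt else None
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path.name} row {lineno}: non-numeric field ({exc})")
            if kind in BETA_KINDS and endpoint is None:
                raise ParseError(f"{path.name} row {lineno}: beta line lacks endpoint_mev")
            try:
                lines.append(EmissionLine(kind, energy, yield_, endpoint))
            except InvalidArgumentError as exc:
                raise ParseError(f"{path.name} row {lineno}: {exc}")
    if header is None or not lines:
        raise ParseError(f"{path.name}: no emission lines found")
    name = name or meta.get("name") or path.stem
    if half_life is None:
        if "half_life_h" not in meta:
            raise ParseError(f"{path.name}: half_life_h metadata missing and not supplied")
        half_life = float(meta["half_life_h"])
    return Radionuclide(name=name, half_life=half_life, lines=tuple(lines))


def _data_path(filename: str) -> Path:
    return Path(resources.files("mousedosim.data") / filename)


def tb152() -> Radionuclide:
    """Packaged Tb-152 line list (17.5 h half-life, beta+ mean 1.140 MeV)."""
    return load_line_list(_data_path("tb152.csv"))


def in111() -> Radionuclide:
    """Packaged In-111 line list (67.32 h half-life)."""
    return load_line_list(_data_path("in111.csv"))


def toy_nuclide() -> Radionuclide:
    """Three-line toy nuclide used in tests and examples."""
    return load_line_list(_data_path("toy3.csv"))
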