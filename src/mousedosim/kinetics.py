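"""Normalized time-activity curves, mono-exponential fits, TIACs, and the
cross-isotope physical-decay extrapolation.

A normalized time-activity curve (nTAC) is the fraction of the administered
activity found in a compartment as a function of time post-injection.  The
values are deliberately NOT decay-corrected: they embed the physical decay
of the measured label, because the cross-isotope scale factor
``SF(t) = exp(-lambda_target t)/exp(-lambda_source t)`` only converts
between labels when the physical decay is still in the curve.  The
mono-exponential fit ``nA(t) = A0 exp(-lambda t)`` therefore estimates the
*effective* rate (biological clearance + physical decay), and the
time-integrated activity coefficient is the closed-form integral
``TIAC = A0 / lambda`` over [0, infinity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr  # noqa: F401  (kept for API users)

from .errors import (
    DataInconsistencyError,
    DegenerateFitError,
    FitError,
    InvalidArgumentError,
)
from .nuclides import Radionuclide, physical_scale_factor

#: nA above this is physically implausible and triggers a warning
_NA_WARN_LEVEL = 1.5

#: tolerated negative rest-of-body remainder, as a fraction of whole-body TIAC
_ROB_DEFICIT_TOL = 0.02


@dataclass(frozen=True)
class TimeActivitySample:
    """One nTAC point: time (h), fraction of injected activity, dispersion."""

    t: float
    na: float
    sd: float = 0.0
    n_animals: int = 1

    def __post_init__(self):
        if self.t < 0:
            raise InvalidArgumentError(f"sample time must be >= 0, got {self.t}")
        if self.na < 0:
            raise InvalidArgumentError(f"nA must be >= 0, got {self.na}")
        if self.sd < 0:
            raise InvalidArgumentError(f"sd must be >= 0, got {self.sd}")
        if self.na > _NA_WARN_LEVEL:
            warnings.warn(
                f"nA = {self.na:.3g} exceeds {_NA_WARN_LEVEL} of the injected "
                "activity; physically implausible",
                stacklevel=2,
            )


@dataclass(frozen=True)
class NTAC:
    """Ordered nTAC of one compartment, tagged with the measured nuclide."""

    compartment: str
    samples: tuple
    nuclide: Optional[Radionuclide] = None

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(self.samples))
        ts = [s.t for s in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
            raise InvalidArgumentError(
                f"{self.compartment}: sample times must be strictly increasing"
            )

    @property
    def t(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])

    @property
    def na(self) -> np.ndarray:
        return np.array([s.na for s in self.samples])

    @property
    def sd(self) -> np.ndarray:
        return np.array([s.sd for s in self.samples])

    def with_values(self, na, sd=None) -> "NTAC":
        sd = self.sd if sd is None else sd
        samples = tuple(
            TimeActivitySample(s.t, float(v), float(e), s.n_animals)
            for s, v, e in zip(self.samples, na, sd)
        )
        return replace(self, samples=samples)


@dataclass(frozen=True)
class MonoExpFit:
    """Mono-exponential fit nA(t) = A0 exp(-lambda t)."""

    a0: float
    lam: float
    r2: float = float("nan")

    def __post_init__(self):
        if self.a0 < 0:
            raise InvalidArgumentError(f"A0 must be >= 0, got {self.a0}")
        if not self.lam > 0:
            raise InvalidArgumentError(f"lambda must be > 0, got {self.lam}")

    def __call__(self, t):
        return self.a0 * np.exp(-self.lam * np.asarray(t, dtype=float))


@dataclass
class TIACSet:
    """Per-source TIACs (MBq h/MBq) with whole-body and rest-of-body slots."""

    organs: dict
    whole_body: Optional[float] = None
    rest_of_body: Optional[float] = None

    def __post_init__(self):
        for name, v in self.organs.items():
            if v < 0:
                raise InvalidArgumentError(f"TIAC for {name!r} must be >= 0")

    def sources(self) -> dict:
        """Organs plus rest_of_body (when computed), for the dose engine."""
        out = dict(self.organs)
        if self.rest_of_body is not None:
            out["rest_of_body"] = self.rest_of_body
        return out


# ---------------------------------------------------------------------------
# building nTACs
# ---------------------------------------------------------------------------


def build_ntac(
    times: Sequence[float],
    activities_mbq: Sequence[float],
    injected_mbq: float,
    compartment: str,
    nuclide: Optional[Radionuclide] = None,
) -> NTAC:
    """nTAC for a single animal: organ activity / administered activity."""
    if not injected_mbq > 0:
        raise InvalidArgumentError("injected activity must be > 0")
    times = np.asarray(times, dtype=float)
    acts = np.asarray(activities_mbq, dtype=float)
    if times.shape != acts.shape:
        raise InvalidArgumentError("times and activities must have equal length")
    if np.any(np.isnan(acts)):
        raise InvalidArgumentError(f"{compartment}: missing activity values")
    samples = tuple(
        TimeActivitySample(float(t), float(a / injected_mbq)) for t, a in zip(times, acts)
    )
    return NTAC(compartment=compartment, samples=samples, nuclide=nuclide)


def cohort_ntac(
    table: pd.DataFrame,
    compartment: str,
    nuclide: Optional[Radionuclide] = None,
) -> NTAC:
    """Cohort nTAC (mean +- 1 SD per sacrifice time) from a biodistribution
    table with columns ``animal_id, compartment, time_h`` and either ``nA``
    or ``activity_mbq`` + ``injected_mbq``."""
    sub = table[table["compartment"] == compartment]
    if sub.empty:
        raise InvalidArgumentError(f"no rows for compartment {compartment!r}")
    if "nA" in sub.columns:
        values = sub["nA"]
    elif {"activity_mbq", "injected_mbq"}.issubset(sub.columns):
        values = sub["activity_mbq"] / sub["injected_mbq"]
    else:
        raise InvalidArgumentError(
            "table needs an nA column or activity_mbq + injected_mbq"
        )
    sub = sub.assign(_na=values)
    grouped = sub.groupby("time_h")["_na"]
    samples = tuple(
        TimeActivitySample(
            float(t), float(g.mean()), float(g.std(ddof=1)) if len(g) > 1 else 0.0,
            n_animals=len(g),
        )
        for t, g in sorted(grouped, key=lambda kv: kv[0])
    )
    return NTAC(compartment=compartment, samples=samples, nuclide=nuclide)


def read_biodistribution_csv(path) -> pd.DataFrame:
    """Biodistribution CSV: one row per organ per animal per time point."""
    df = pd.read_csv(path, comment="#")
    required = {"animal_id", "compartment", "time_h"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(
            f"biodistribution table must have columns {sorted(required)}"
        )
    return df


# ---------------------------------------------------------------------------
# fitting and integration
# ---------------------------------------------------------------------------


def _loglinear_init(t: np.ndarray, na: np.ndarray):
    pos = na > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(na[pos]), 1)
        return math.exp(intercept), max(-slope, 1e-6)
    return float(na.max()), 1e-2


def fit_monoexp(ntac: NTAC) -> MonoExpFit:
    """Unweighted nonlinear least squares of A0 exp(-lambda t), lambda > 0.

    Initialized by log-linear regression on the positive points; raises
    :class:`DegenerateFitError` for an all-zero curve and :class:`FitError`
    (carrying the initial estimates) on non-convergence.
    """
    t, na = ntac.t, ntac.na
    if len(t) < 2:
        raise InvalidArgumentError(
            f"{ntac.compartment}: at least 2 samples required for fitting"
        )
    if not np.any(na > 0):
        raise DegenerateFitError(f"{ntac.compartment}: all nA values are zero")
    a0_init, lam_init = _loglinear_init(t, na)
    try:
        popt, _ = curve_fit(
            lambda tt, a, l: a * np.exp(-l * tt),
            t,
            na,
            p0=[a0_init, lam_init],
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(
            f"{ntac.compartment}: mono-exponential fit did not converge ({exc})",
            initial=(a0_init, lam_init),
        )
    a0, lam = float(popt[0]), float(popt[1])
    resid = na - a0 * np.exp(-lam * t)
    ss_res = float(resid @ resid)
    ss_tot = float(((na - na.mean()) ** 2).sum())
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-30 else 0.0
    return MonoExpFit(a0=a0, lam=lam, r2=r2)


def tiac(fit: MonoExpFit) -> float:
    """Closed-form integral of the fit over [0, infinity): A0/lambda (MBq h/MBq)."""
    if not fit.lam > 0:
        raise InvalidArgumentError("lambda must be > 0 for an integrable curve")
    return fit.a0 / fit.lam


def tiac_trapezoid_tail(ntac: NTAC, fit: MonoExpFit) -> float:
    """Alternative reading: trapezoid over the samples (with the fitted value
    at t=0), analytic exponential tail beyond the last sample."""
    t, na = ntac.t, ntac.na
    tt = np.concatenate(([0.0], t)) if t[0] > 0 else t
    vv = np.concatenate(([fit.a0], na)) if t[0] > 0 else na
    head = float(np.trapezoid(vv, tt))
    tail = float(fit(t[-1])) / fit.lam
    return head + tail


def rest_of_body(tiacs: TIACSet) -> TIACSet:
    """Fill in rest_of_body = whole_body - sum(organ TIACs).

    A small negative remainder (down to 2% of whole-body) is clamped to zero
    with a warning; a larger deficit raises :class:`DataInconsistencyError`.
    Conservation holds exactly afterwards (organs + rest = whole body, up to
    the clamp).
    """
    if tiacs.whole_body is None:
        raise InvalidArgumentError("whole-body TIAC required for rest-of-body")
    remainder = tiacs.whole_body - sum(tiacs.organs.values())
    if remainder < 0:
        if remainder < -_ROB_DEFICIT_TOL * tiacs.whole_body:
            raise DataInconsistencyError(
                f"organ TIACs exceed whole-body TIAC by "
                f"{-remainder:.4g} MBq h/MBq (> {_ROB_DEFICIT_TOL:.0%} of whole body)"
            )
        warnings.warn(
            f"rest-of-body remainder {remainder:.3g} clamped to 0", stacklevel=2
        )
        remainder = 0.0
    return TIACSet(
        organs=dict(tiacs.organs), whole_body=tiacs.whole_body, rest_of_body=remainder
    )


def extrapolate_nuclide(ntac: NTAC, target: Radionuclide) -> NTAC:
    """Rescale a measured nTAC to another label via the physical scale factor.

    Pointwise ``nA_target(t) = nA_source(t) x SF(t)``; dispersions scale the
    same way.  Decay-corrected biology is invariant under the operation.
    """
    if ntac.nuclide is None:
        raise InvalidArgumentError("source nTAC must be tagged with its nuclide")
    if ntac.nuclide.name == target.name:
        warnings.warn(
            f"extrapolation to the same nuclide {target.name}: no-op", stacklevel=2
        )
        return replace(ntac, nuclide=target)
    sf = np.array(
        [physical_scale_factor(s.t, ntac.nuclide, target) for s in ntac.samples]
    )
    out = ntac.with_values(ntac.na * sf, ntac.sd * sf)
    return replace(out, nuclide=target)


@dataclass(frozen=True)
class BandFits:
    """Fits of the cohort mean and the mean +- 1 SD envelope curves."""

    mean: MonoExpFit
    upper: MonoExpFit
    lower: Optional[MonoExpFit]  # None when the lower band is identically zero


def fit_bands(ntac: NTAC) -> BandFits:
    """Three mono-exponential fits: mean, mean+1SD, mean-1SD (floored at 0).

    A lower band that degenerates to all zeros yields ``lower=None`` (with a
    warning) rather than failing the whole cohort.
    """
    mean_fit = fit_monoexp(ntac)
    upper_fit = fit_monoexp(ntac.with_values(ntac.na + ntac.sd))
    lower_na = np.maximum(ntac.na - ntac.sd, 0.0)
    try:
        lower_fit = fit_monoexp(ntac.with_values(lower_na))
    except DegenerateFitError:
        warnings.warn(
            f"{ntac.compartment}: mean-1SD band is identically zero; "
            "no lower fit",
            stacklevel=2,
        )
        lower_fit = None
    return BandFits(mean=mean_fit, upper=upper_fit, lower=lower_fit)


def sensitivity_drop_last(ntac: NTAC) -> float:
    """Percent change of the TIAC when the last sample is excluded:
    |TIAC(all) - TIAC(drop last)| / TIAC(all) x 100."""
    if len(ntac.samples) < 3:
        raise InvalidArgumentError("at least 3 samples needed to drop one")
    full = tiac(fit_monoexp(ntac))
    truncated = replace(ntac, samples=ntac.samples[:-1])
    reduced = tiac(fit_monoexp(truncated))
    return abs(full - reduced) / full * 100.0
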