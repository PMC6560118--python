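# Methods

This note documents the models, parameters, numerical choices and
limitations of `mousedosim`, in the order the pipeline uses them.

## Dose formalism and units

Absorbed dose to a target region is the sum over source regions of the
time-integrated activity coefficient (TIAC, MBq·h per MBq administered)
times a dose factor DF (mGy per MBq·h). One conversion constant set is
defined once (`mousedosim.units`): 1 MBq·h = 3.6×10⁹ decays and
1 MeV = 1.602×10⁻¹³ J, giving the closed form

    DF = E_abs [MeV/decay] × 1.602e-13 × 3.6e9 / m [kg] × 10³  mGy/(MBq·h),

so 1 MeV per decay fully absorbed in 1 g is 576.7 mGy/(MBq·h). Time is in
hours everywhere, energies in MeV, activities in MBq, concentrations in
kBq/mL, masses in g, image coordinates in mm, ellipsoid semi-axes in cm.

## Kinetics

Normalized time-activity curves (nA = region activity / administered
activity) deliberately **embed physical decay**. This is required for the
cross-isotope scale factor SF(t) = exp(−λ_target·t)/exp(−λ_source·t) to be
a pointwise multiplication, and it means a fitted rate is the *effective*
rate λ_eff = λ_bio + λ_phys.

Fits are unweighted nonlinear least squares of A₀·e^(−λt) with λ > 0,
initialized by log-linear regression on the positive points. The choice of
unweighted residuals follows from the data scale (fractions spanning ~2
decades over a schedule of 3–4 points); it makes the TIAC insensitive to
the low-count tail, which is also why excluding the 96 h point moves TIACs
by well under 6% in the default scenario (~6 effective half-lives of tail
coverage for the slowest compartment).

TIAC = A₀/λ integrates the fit over [0, ∞). The curve is treated as
mono-exponential from injection onward; no uptake phase is modeled. An
alternative reading (trapezoid over the samples plus analytic tail) is
available as `tiac_method="trapezoid+tail"`.

Rest of body = whole body − Σ source organs, computed after fitting so the
identity holds exactly. A negative remainder up to 2% of the whole-body
TIAC is clamped to zero with a warning (fit noise); a larger deficit
raises an error. For the ±1 SD band curves of the biodistribution route
any negative remainder is clamped, since band envelopes of independently
fitted organs need not be jointly consistent with the whole-body band.

The imaging route fits each animal separately and averages the resulting
doses (mean ± SD across animals); the biodistribution route fits the
cohort mean and the mean ± 1 SD envelopes, reporting half the spread of
the two band doses as the dispersion.

## Calibration and VOI quantification

A uniformly filled phantom with known concentration A_c,bg defines the
scaling factor (S_bg/A_c,bg)⁻¹ applied globally to all acquisitions (a
per-acquisition mode would only differ if camera sensitivity drifted;
the generator models none). VOI activities are voxel sums times voxel
volume; masks are voxel-aligned with no partial-voxel weighting. Organ
masses are VOI volume × tissue density from a packaged ICRP-110-derived
table (soft tissue ≈ 1.00–1.06 g/mL, lungs 0.26 g/mL), every entry
overridable. **No partial-volume correction is applied anywhere**: the
spill-out/spill-in bias of finite resolution is part of the measurement
and is reproduced by the generator so it can be quantified.

## Dose engine

Self-dose mass rescaling uses m_ref/m_actual for the electron
(non-penetrating) component and (m_ref/m_actual)^(2/3) for the photon
component (surface-to-volume scaling of the photon self-absorbed
fraction); a DF matrix without the component split scales the whole
self-dose entry by 1/m (non-penetrating approximation). Cross-organ terms
are left unscaled — how reference codes rescale penetrating cross-fire is
undocumented, and the effect is second-order at mouse organ separations.

The merged intestine VOI is partitioned 75% small / 25% large intestine in
both TIAC and mass, matching the mass proportions of the 25 g mouse
phantom; the partition is exactly conservative.

The packaged target×source DF matrix (`toy_mouse_dfm*.csv`) is a
**synthetic** stand-in with realistic magnitudes (electron-dominated
self-dose, weak photon cross-fire); any published rodent DF table in the
same CSV layout plugs in through `DoseFactorMatrix.from_csv`. A
`rest_of_body` source column is used directly when present; otherwise a
`total_body` column is used and flagged in the report.

Tumor doses use the sphere model: a packaged reference DF table
(log-log interpolation in mass, valid 0.05–20 g) or the analytic
ellipsoid model below. The study-relevant tumor masses (~0.5–1 g) sit
well inside the tabulated grid.

## Analytical ellipsoid absorbed-fraction model

The model computes φ(E) — the fraction of emitted energy absorbed in a
uniform-activity, unit-density convex body — per emission kind, and
assembles DF = Σ yᵢEᵢφᵢ / m over the line list.

**Electrons** (β mean energies, conversion and Auger lines): straight-ray
geometric escape with a scattering correction. An electron of energy E
deposits its energy along an effective path d·R_CSDA(E); the energy left
after a ray of length ℓ exits the body follows the residual-CSDA-energy
profile compressed onto the effective path. φ is the mean deposited
fraction over uniform source points and isotropic directions, evaluated by
64×64 Gauss–Legendre quadrature on the equivalent sphere (radius = ¾ of
the body's mean chord 4V/S; exact for spheres). The detour coefficient
d = 0.70 is the single calibrated constant of the model: pure straight
CSDA tracks (d = 1) overestimate escape because multiple scattering
shortens penetration, and d was fixed once against published Tb-152
unit-density sphere dose factors from an independent analytic ellipsoid
code, after which the model reproduces that table to within 5% over
0.1–10 g. Both coefficient tables (ESTAR-style CSDA ranges, NIST-style
μ_en of water, log-log interpolated) and d live in
`AbsorbedFractionParams`, so a different published parametrization can be
dropped in as data.

**Photons** (γ, x-rays, annihilation quanta): attenuation
1 − exp(−μ_en·ℓ) averaged over the body's chord-length distribution
(μ-randomness; for the matched sphere f(ℓ) = ℓ/2r², 128-point
quadrature). Using the energy-absorption coefficient μ_en along the whole
chord — rather than the total attenuation coefficient and an escape
integral from the first interaction — partially compensates the neglected
redeposition of scattered photons, the same convention published analytic
ellipsoid models adopt; the rigorous interior-ray first-flight integral
underestimates photon self-absorption noticeably at multi-gram sizes.
Photon energies outside the 0.01–3 MeV table raise a domain error.

Annihilation photons (2 × 0.511 MeV per β⁺) are appended automatically
unless a 511 keV photon is already listed (the packaged ¹⁵²Tb list
includes it explicitly, so nothing is double counted). β lines are
evaluated at their mean energy by default; a binned spectrum attached to a
line is integrated bin by bin.

The packaged ¹⁵²Tb and ¹¹¹In line lists are synthetic compilations
assembled from evaluated-nuclear-data summaries (the files say so); the
¹⁵²Tb β⁺ branch matches the published summary (mean 1.140 MeV, 20.3%,
endpoint 2.97 MeV) and is pinned by a test. Decay-chain daughters are
ignored throughout.

## Synthetic-data generator

The generator defines the study conditions the tests and acceptance runs
use; it emulates:

* **Dissection cohorts** — sacrifice times 4/24/48/96 h with group sizes
  3/5/4/3, each organ following A₀·e^(−λ_bio·t) times physical decay,
  with multiplicative lognormal inter-animal noise of unit mean and
  CV = 10%. Ground-truth TIACs are analytic: A₀/(λ_bio + λ_phys).
* **Imaging series** — a digital mouse of ellipsoidal organs inside an
  ellipsoidal body on a 0.5 mm isotropic grid, imaged at 4/24/48 h
  (4 animals); painted concentration maps are blurred with a Gaussian PSF
  (σ = 0.6 mm, i.e. ~1.4 mm FWHM, an effective scanner-plus-motion
  resolution) and degraded with Poisson noise (2 expected counts per
  kBq/mL per voxel); a gain of 1/205 converts concentration to raw
  signal, matched by the phantom measurement (8.2 MBq in 20 mL →
  410 kBq/mL). VOI masks are the *unblurred* organ supports.

The default scenario is a liver-dominant antibody: A₀ fractions
heart 0.005, lungs 0.008, liver 0.30, kidneys 0.025, intestines 0.08,
tumor 0.055, carcass 0.44, excreta 0.075 (decays outside the body), with
biological rates 0.045/0.040/0.008/0.010/0.012/0.004/0.015/0.030 h⁻¹.
The fractions are sized so organ concentrations are realistic in %IA/g
terms: the liver is ~10× hotter per mL than heart or lungs, which is what
makes hepatic spill-in dominate thoracic VOIs once blood activity has
cleared. The liver dome is deliberately broad and flat with the heart and
lungs seated ~0.2 mm above it, emulating the diaphragm interface; a
tangent-point contact would make spill-in a negligible artifact of the
geometry. The dissection cohort is labeled ¹¹¹In and imaging ¹⁵²Tb with
shared biology — the cross-isotope design the pipeline exists for.

The whole-body VOI is the body support dilated by 3 mm so that PSF tails
remain inside it; a VOI drawn exactly at the skin would lose ~2% of
counts and confound the conservation check with a segmentation artifact.

What the generator does **not** model: anatomical organ shapes,
attenuation/scatter/randoms, reconstruction artifacts, circulating-blood
background, respiratory motion beyond the inflated PSF, uptake phases
(curves decrease monotonically from t = 0), or dissection losses. Passing
recovery tests therefore demonstrates correctness of the estimation
chain under the stated noise and resolution model, not accuracy on real
scanner data.

## Numerical choices

* Log-log interpolation for all physical tables (CSDA, μ_en, sphere DF).
* Gauss–Legendre orders: 64 (source radius) × 64 (direction cosine) for
  electrons, 128 chord nodes for photons; φ clamped to [0, 1].
* curve_fit bounds λ ∈ (10⁻¹², ∞); two-point curves are fitted exactly.
* R² is reported per fit; an all-zero curve raises a degenerate-fit
  error, non-convergence raises a fit error carrying the initial
  estimates.
* Lognormal noise uses σ² = ln(1 + CV²) with mean −σ²/2, so the noise
  factor has unit mean at every CV.
* All randomness flows from explicit integer seeds (cohort and phantom
  specs carry their own; per-animal imaging seeds are seed + animal
  index).

## Problem sizes

The test suite and acceptance script use: 200 seeded cohorts (1400 organ
fits) for TIAC recovery; 500 cohorts for rate-coverage; one digital
mouse per PSF setting (76×72×152 voxels, 3 time points) for imaging
checks; 100 random parameter draws for the TIAC quadrature oracle; and
40 000-sample Monte Carlo oracles for the absorbed-fraction checks. A
full run of suite plus acceptance script completes in well under a
minute on one CPU.

## Known limitations

* The electron φ model is a one-coefficient surrogate for full transport;
  its stated accuracy (5%, verified 0.1–10 g for ¹⁵²Tb) degrades for very
  small bodies (≲0.05 g) where track-structure detail matters, and for
  media far from unit density.
* Photon φ ignores buildup beyond the μ_en convention; adequate below
  ~10 g of soft tissue, increasingly optimistic for larger bodies.
* Heart VOI semantics: imaging "heart" is wall + contents; a phantom's
  "heart wall" target is not the same region, and reports should not be
  compared across that boundary silently.
* The tumor's possible uptake phase is not modeled (mono-exponential
  decrease from t = 0), mirroring the fitting choice of the imaging
  route it reimplements.
* Printed-table reference values (sphere DF table, published mean doses)
  carry their sources' rounding.
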