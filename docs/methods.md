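# Methods

## The model

Skin is represented as two plane-parallel turbid layers in air: a thin
epidermis (0.06 mm) whose only absorber is melanin, over a dermis
(4.94 mm) absorbing through oxygenated hemoglobin, deoxygenated
hemoglobin, and bilirubin.  Both layers share refractive index 1.4 and
the same reduced scattering spectrum.  Absorption coefficients are built
from molar extinction coefficients as `mua(λ) = 2.303 · C · ε(λ)` with
C in mol/L; the bilirubin term is additionally scaled by an empirical
optical-effectiveness factor `f_bil = 0.2`.  The packaged extinction and
reduced-scattering table covers 460–590 nm at 10 nm (14 bands), a window
chosen because bilirubin absorbs strongly near 460 nm, hemoglobin shows
oxygenation-sensitive structure with isosbestic points at 570/585 nm,
and melanin decays smoothly across the band.

Concentration conventions: melanin in vol.% of epidermis occupied by
melanosomes (1 vol.% = 2.14×10⁻³ M), hemoglobin in vol.% of dermis
occupied by whole blood (100 vol.% = 2.32×10⁻³ M, i.e. 150 g/L at 44%
hematocrit; 1 vol.% = 2.32×10⁻⁵ M), bilirubin in mg/dl of whole blood
(molar mass 584.67 g/mol).  An alternative, ten-fold more dilute blood
convention (0.2 vol.% ↔ 4.65×10⁻⁷ M) circulates in parts of the
literature; it is available as
`UnitConventions.dilute_blood_convention()` but is not the default
because only the 150 g/L reading is consistent with standard whole-blood
composition.

### Provenance of the packaged basis spectra

The packaged table stores what the source literature actually
tabulates, one column per chromophore:

- **melanin** — the absorption coefficient of a melanosome (cm⁻¹),
  following the familiar ~λ⁻³·⁴⁸ power law (897 cm⁻¹ at 460 nm falling
  to 391 at 590); the epidermis absorption at `Cm` vol.% is that curve
  proportioned by `Cm/100`;
- **oxygenated / deoxygenated hemoglobin** — the absorption
  coefficients of fully oxygenated and fully deoxygenated whole blood
  (cm⁻¹ at 150 g/L): the oxy curve carries the classic 540/578 nm
  double peak with the 560 nm dip, the deoxy curve the single ~555 nm
  peak, and the two cross at the 570 and ~585 nm isosbestic points;
- **bilirubin** — the molar extinction coefficient (cm⁻¹ M⁻¹), peaking
  at/below 460 nm (≈52,900 there) and negligible beyond ~530 nm.

The loader converts the absorption-coefficient columns into effective
molar extinctions (`eps = mua / (2.303 · C_pure)` with pure-phase
molarities 0.214 M for melanosome and 2.32×10⁻³ M for whole blood), so
the uniform builders `mua = 2.303·C·eps` reproduce the tabulated
coefficients exactly at 100 vol.% — for the hemoglobins this recovers
the standard literature molar extinction spectra.  A replacement table
can be supplied through `load_chromophore_table(path)` and is tracked
by a content hash so calibrations are never applied across mismatched
tables.

## Forward model: Monte Carlo photon transport

`dermospec.mc` implements the standard weighted-photon hop–drop–spin
random walk for multilayer slabs: step lengths from the free-path
distribution with dimensionless-remainder carry-over across boundaries,
weight deposition `w·mua/mut` per interaction, Henyey–Greenstein
scattering, unpolarized Fresnel reflection/refraction at index
mismatches, and Russian-roulette termination (threshold 10⁻⁴, survival
1/10).  Only the reduced scattering coefficient is specified for skin,
so the engine defaults to the similarity relation `g = 0`,
`mus = musp`; anisotropic runs set `mus = musp/(1−g)` and are verified
to agree with the isotropic default within 2% in the diffusion regime.
Specular reflection at the air surface (2.78% at n = 1.4) is tallied
separately and excluded from reported reflectance by default, matching
crossed-polarizer measurement geometry.  Photons crossing the bottom of
the dermis are tallied as transmitted.

Energy conservation is enforced as an exact floating-point identity,
not a statistical statement: weight destroyed and created by roulette is
booked explicitly, so specular + diffuse + absorbed + transmitted +
roulette-killed − roulette-boost equals the launched weight to ~10⁻¹²
in every run.

When every layer scatters isotropically, transport is one-dimensional
in depth and the Fresnel angle depends only on the direction cosine, so
the kernel tracks just `uz`; this is exact, not an approximation.

### Path-length reweighting for grid sweeps

The calibration requires thousands of (combination, wavelength)
reflectance values over a grid in which only absorption varies: at a
fixed wavelength every combination shares the same scattering problem.
`sweep_grid(..., method="pathlength")` therefore generates one
zero-absorption path ensemble per wavelength, records each photon's
path length in epidermis and dermis, and evaluates any combination as

    Rd = (1 − Rsp) · mean over paths( escaped · exp(−mua_e·L_e − mua_d·L_d) ),

the classic "white Monte Carlo" estimator, exact in expectation.
Standard errors come from 20 block means.  This makes full-statistics
sweeps (5×10⁶ photons/wavelength) feasible in minutes on one CPU.  The
default `method="analog"` keeps one independent simulation per cell
with per-cell seeds; the two estimators are cross-checked against each
other (within combined Monte Carlo error) in the test suite.  One
consequence of sharing ensembles is that Monte Carlo noise is
correlated across grid rows at the same wavelength; the recovery study
therefore always simulates its validation grid from a disjoint seed, so
reported recovery is out-of-sample with respect to the noise.

## The two-stage inversion

Stage 1 (spectral unmixing) converts reflectance to decadic attenuation
`A = −log10 r` and fits, by ordinary least squares with intercept,

    A(λ) ≈ am·εm(λ) + aoh·εoh(λ) + adh·εdh(λ) + abil·εbil(λ) + a0.

The coefficients mix concentration with mean photon path length — which
itself depends on every absorber — so no coefficient is a concentration,
and the latent path lengths are never computed.  No regularization or
wavelength weighting is applied (a weights hook exists, default
uniform); collinearity of the four basis spectra on 14 points is
reported through the design condition number but not "fixed".  The OLS
intercept identity (a0 equals the mean attenuation minus the
extinction-mean-weighted coefficients) holds to machine precision and is
used as a fit audit.

Stage 2 (calibration) simulates the full 1800-combination grid
(melanin 1–10 vol.%, bilirubin {0,1,5,10,15,20} mg/dl, total hemoglobin
0.2–1.0 vol.%, saturation 0–100%), unmixes every spectrum, and fits four
independent OLS conversion vectors mapping `a = (1, am, aoh, adh, abil,
a0)` to each concentration, in vol.% for melanin and the hemoglobins and
mg/dl for bilirubin.  The vectors are fitted once, serialized with
provenance (seed, photon count, grid hash, table version), and reused;
estimation never triggers simulation.  Predictions may be negative for
out-of-range spectra and are reported raw, with an optional
clip-at-zero post-processor.  Total hemoglobin and oxygen saturation
follow as `Cth = Coh + Cdh` and `StO2 = 100·Coh/Cth`; saturation is
flagged undefined (NaN) when total hemoglobin is non-positive.

## Problem sizes

The recovery study runs at the study-design photon count of 5×10⁶ per
wavelength — feasible on one CPU because of the path-length-reweighting
sweep — with the full 1800-row training grid and the full 300-row
validation grid (saturation fixed at 60%, independent seeds).  The
package's own acceptance bar for that study is a Pearson correlation of
at least 0.95 between given and estimated values for each chromophore;
the underlying comparison is qualitative, so the threshold is this
artifact's documented choice.  The hemoglobin information in the
spectra is the subtlest of the four signals (dermal blood mua of
0.25–3 cm⁻¹ against scattering of 30–65 cm⁻¹), which is why full
photon statistics are kept rather than scaled down.

Unit and property tests use desk-scale photon counts (10³–10⁵) chosen
so each check resolves its effect within stated Monte Carlo tolerances.

## What the synthetic data does and does not emulate

All test inputs are generated by the forward model itself.  The
generator reproduces the geometry, optical constants, and concentration
ranges of the study design, including Monte Carlo shot noise at the
configured photon count.  It does not add instrument noise, stray or
ambient light, spectrometer wavelength error, dark current, skin
curvature or surface roughness, chromophores outside the four modelled
ones, or depth-dependent scattering differences between epidermis and
dermis (a single reduced-scattering spectrum is used for both).  A
multiplicative Gaussian noise hook exists on the fixture factory for
robustness experiments but is off by default — no measurement-noise
model is part of the design.  Passing recovery on
synthetic data therefore demonstrates the internal consistency of the
inversion under the model's own assumptions, not field accuracy on real
skin.

## Numerical choices and degenerate inputs

- Reflectance must be strictly positive for attenuation; offending
  wavelengths are named in the error.  Values above 1 warn; in cube
  processing, pixels above a configurable cap (default 1.2, specular
  glint) or with non-positive bands are masked, never guessed.
- Spectra on finer or offset grids are linearly interpolated onto the
  14-point analysis grid; grid-aligned input passes through
  bit-identically (exact subset selection).
- Transparent layers (mut = 0) propagate photons ballistically to the
  boundary; photons with zero weight terminate immediately.
- Seeds: every sweep cell (analog) or wavelength ensemble (pathlength)
  receives a seed derived deterministically from the base seed via
  `numpy` seed sequences; repeat runs are bit-identical.
- ENVI cubes are band-sequential float32 by default; BIL/BIP are read.
  Band wavelengths must be present in the header — band positions are
  never inferred from file order.

## Known limitations

- The extinction table's absolute scale is taken as packaged; estimates
  are only meaningful relative to calibrations built from the same
  table (enforced via the table version hash).
- The stage-2 map is linear in the coefficients; strongly out-of-grid
  concentrations extrapolate linearly and can go negative.
- Oxygen saturation estimates inherit the weak hemoglobin signal; at
  low total hemoglobin the saturation ratio is noisy even at full
  photon statistics.
- No polarization, fluence maps, spatially- or time-resolved
  reflectance, or curved geometries.
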