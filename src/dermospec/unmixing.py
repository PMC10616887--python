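"""Attenuation spectra and stage-1 regression (spectral unmixing).

A measured diffuse reflectance spectrum ``r(lambda)`` -- the ratio of
tissue intensity to white-standard intensity -- is converted to an
attenuation spectrum ``A(lambda) = -log10 r(lambda)`` and regressed by
ordinary least squares onto the four chromophore extinction spectra
plus an intercept:

    A(lambda) = am*eps_m + aoh*eps_oh + adh*eps_dh + abil*eps_bil + a0.

The regression coefficients mix concentration and mean optical path
length (which itself depends on every absorber), so they are not
concentrations; the stage-2 calibration (:mod:`dermospec.calibration`)
maps them to concentrations with conversion vectors trained on
simulated spectra.  The OLS intercept satisfies the usual identity

    a0 = mean(A) - mean(eps_m)*am - mean(eps_oh)*aoh
         - mean(eps_dh)*adh - mean(eps_bil)*abil,

which is exposed for auditing fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import ChromophoreSpectra

__all__ = [
    "ReflectanceSpectrum",
    "AttenuationSpectrum",
    "RegressionCoefficients",
    "ratio_spectrum",
    "attenuation",
    "fit_attenuation",
]

#: Warn when a fit's design-matrix condition number exceeds this.
DEFAULT_CONDITION_CAP = 1e12


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Diffuse reflectance fraction per wavelength."""

    wavelengths_nm: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        wl = np.atleast_1d(np.asarray(self.wavelengths_nm, dtype=float))
        r = np.atleast_1d(np.asarray(self.r, dtype=float))
        if wl.shape != r.shape:
            raise ValueError("wavelength and reflectance shapes differ")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(r > 1.0 + 1e-9):
            warnings.warn("reflectance exceeds 1; check the white reference",
                          stacklevel=2)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "r", r)


@dataclass(frozen=True)
class AttenuationSpectrum:
    """Decadic attenuation -log10(r) per wavelength."""

    wavelengths_nm: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        wl = np.atleast_1d(np.asarray(self.wavelengths_nm, dtype=float))
        a = np.atleast_1d(np.asarray(self.A, dtype=float))
        if wl.shape != a.shape:
            raise ValueError("wavelength and attenuation shapes differ")
        if not np.all(np.isfinite(a)):
            raise ValueError("attenuation must be finite everywhere")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "A", a)


@dataclass(frozen=True)
class RegressionCoefficients:
    """Stage-1 coefficients and fit diagnostics.

    The coefficients are dimensionless mixtures of concentration and
    path length; ``as_vector`` prepends the constant 1 and appends the
    intercept, giving the 6-vector consumed by the stage-2 conversion.
    """

    am: float
    aoh: float
    adh: float
    abil: float
    a0: float
    residual_norm: float = np.nan
    condition_number: float = np.nan

    def as_vector(self) -> np.ndarray:
        return np.array([1.0, self.am, self.aoh, self.adh, self.abil, self.a0])


def ratio_spectrum(it, istd, wavelengths_nm, dark=None) -> ReflectanceSpectrum:
    """Reflectance as the elementwise ratio of tissue to white-standard intensity.

    ``dark`` is an optional pre-measured dark-frame spectrum subtracted
    from both intensities before the ratio (no dark model is computed).
    """
    it = np.asarray(it, dtype=float)
    istd = np.asarray(istd, dtype=float)
    wl = np.asarray(wavelengths_nm, dtype=float)
    if it.shape != istd.shape or it.shape != wl.shape:
        raise ValueError("intensity spectra and wavelength grid must share a shape")
    if dark is not None:
        dark = np.asarray(dark, dtype=float)
        if dark.shape != it.shape:
            raise ValueError("dark frame must share the intensity grid")
        it = it - dark
        istd = istd - dark
    if np.any(istd <= 0):
        bad = wl[istd <= 0]
        raise ValueError(f"white-standard intensity must be positive; "
                         f"nonpositive at {bad.tolist()} nm")
    return ReflectanceSpectrum(wavelengths_nm=wl, r=it / istd)


def attenuation(r: ReflectanceSpectrum) -> AttenuationSpectrum:
    """``A = -log10 r``, rejecting nonpositive reflectance."""
    if np.any(r.r <= 0):
        bad = r.wavelengths_nm[r.r <= 0]
        raise ValueError(f"reflectance must be positive for attenuation; "
                         f"nonpositive at {bad.tolist()} nm")
    return AttenuationSpectrum(wavelengths_nm=r.wavelengths_nm,
                               A=-np.log10(r.r))


def design_matrix(s: ChromophoreSpectra) -> np.ndarray:
    """OLS design: columns (eps_m, eps_oh, eps_dh, eps_bil, 1)."""
    return np.column_stack([s.eps_m, s.eps_oh, s.eps_dh, s.eps_bil,
                            np.ones(s.n_bands)])


def fit_attenuation(
    A: AttenuationSpectrum,
    s: ChromophoreSpectra,
    weights: np.ndarray | None = None,
    condition_cap: float = DEFAULT_CONDITION_CAP,
) -> RegressionCoefficients:
    """Least-squares fit of an attenuation spectrum onto the extinction basis.

    Parameters
    ----------
    A
        Attenuation on the same wavelength grid as ``s``.
    s
        Extinction basis spectra.
    weights
        Optional per-wavelength weights (default uniform).
    condition_cap
        Condition number above which a collinearity warning is issued.

    Returns
    -------
    RegressionCoefficients
        Coefficients minimizing the (weighted) sum of squared residuals,
        with residual norm and design condition number as diagnostics.
    """
    if A.wavelengths_nm.size != s.n_bands or not np.allclose(
            A.wavelengths_nm, s.wavelengths_nm):
        raise ValueError("attenuation grid does not match the basis grid")
    X = design_matrix(s)
    y = A.A
    if weights is not None:
        wroot = np.sqrt(np.asarray(weights, dtype=float))
        X = X * wroot[:, None]
        y = y * wroot
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix; basis spectra are collinear")
    if cond > condition_cap:
        warnings.warn(f"design condition number {cond:.3g} exceeds "
                      f"{condition_cap:.3g}", stacklevel=2)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return RegressionCoefficients(
        am=float(beta[0]), aoh=float(beta[1]), adh=float(beta[2]),
        abil=float(beta[3]), a0=float(beta[4]),
        residual_norm=float(np.linalg.norm(resid)),
        condition_number=float(cond),
    )


def intercept_identity_residual(coeffs: RegressionCoefficients,
                                A: AttenuationSpectrum,
                                s: ChromophoreSpectra) -> float:
    """Relative residual of the OLS intercept identity (0 for a valid fit)."""
    expected = (A.A.mean()
                - s.eps_m.mean() * coeffs.am
                - s.eps_oh.mean() * coeffs.aoh
                - s.eps_dh.mean() * coeffs.adh
                - s.eps_bil.mean() * coeffs.abil)
    scale = max(abs(expected), abs(coeffs.a0), 1e-30)
    return abs(coeffs.a0 - expected) / scale
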