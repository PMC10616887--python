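"""Chromophore optical constants and concentration/unit conversions.

The analysis operates on a fixed 14-point wavelength grid (460-590 nm,
10 nm step) where the four skin chromophores of interest -- melanin,
oxygenated hemoglobin, deoxygenated hemoglobin, and bilirubin -- have
well-separated spectral signatures: bilirubin peaks near 460 nm,
hemoglobin shows its oxygenation-sensitive structure between 520 and
590 nm (isosbestic points at 570 and 585 nm), and melanin decays
monotonically with wavelength.

Concentration conventions follow the tissue-optics literature:

* melanin as volume percent of the epidermis occupied by melanosomes,
* hemoglobin as volume percent of the dermis occupied by whole blood
  (150 g/L hemoglobin, 44% hematocrit, i.e. 2.32e-3 M at 100 vol.%),
* bilirubin in mg/dl of whole blood.

Absorption coefficients are built from molar extinction coefficients
``eps`` (cm^-1 M^-1) via the decadic-to-natural conversion
``mua = 2.303 * C * eps`` with C in mol/L.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ANALYSIS_GRID_NM",
    "ChromophoreSpectra",
    "ConcentrationSet",
    "UnitConventions",
    "MolarConcentrations",
    "load_chromophore_table",
    "concentrations_to_molar",
    "molar_to_concentrations",
    "epidermis_mua",
    "dermis_mua",
    "arteriovenous_oxygen_saturation",
]

#: The 14-point visible analysis grid, in nanometres.
ANALYSIS_GRID_NM = np.arange(460.0, 591.0, 10.0)

#: ln(10): converts decadic molar extinction to a natural absorption coefficient.
LN10 = 2.303


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Extinction-coefficient basis spectra and reduced scattering on the grid.

    Attributes
    ----------
    wavelengths_nm
        Strictly increasing wavelength grid (nm); 14 points for the
        packaged table.
    eps_m, eps_oh, eps_dh, eps_bil
        Effective molar extinction coefficients (cm^-1 M^-1) of melanin,
        oxy- and deoxyhemoglobin, and bilirubin at each wavelength (see
        :func:`load_chromophore_table` for their provenance).
    musp
        Reduced scattering coefficient (cm^-1) of skin at each wavelength,
        used for both epidermis and dermis.
    version
        Provenance tag of the table; conversion vectors record it so a
        calibration is never applied across mismatched tables.
    """

    wavelengths_nm: np.ndarray
    eps_m: np.ndarray
    eps_oh: np.ndarray
    eps_dh: np.ndarray
    eps_bil: np.ndarray
    musp: np.ndarray
    version: str = ""

    def __post_init__(self) -> None:
        arrays = {
            "wavelengths_nm": np.asarray(self.wavelengths_nm, dtype=float),
            "eps_m": np.asarray(self.eps_m, dtype=float),
            "eps_oh": np.asarray(self.eps_oh, dtype=float),
            "eps_dh": np.asarray(self.eps_dh, dtype=float),
            "eps_bil": np.asarray(self.eps_bil, dtype=float),
            "musp": np.asarray(self.musp, dtype=float),
        }
        n = arrays["wavelengths_nm"].size
        for name, arr in arrays.items():
            if arr.ndim != 1 or arr.size != n:
                raise ValueError(f"{name} must be 1-D with {n} entries")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
            object.__setattr__(self, name, arr)
        if np.any(np.diff(arrays["wavelengths_nm"]) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if not self.version:
            object.__setattr__(self, "version", self._content_hash())

    def _content_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.wavelengths_nm, self.eps_oh, self.eps_dh,
                    self.eps_bil, self.eps_m, self.musp):
            h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
        return "sha256:" + h.hexdigest()[:16]

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    def basis_matrix(self) -> np.ndarray:
        """Columns (eps_m, eps_oh, eps_dh, eps_bil), one row per wavelength."""
        return np.column_stack([self.eps_m, self.eps_oh, self.eps_dh, self.eps_bil])


#: Molar concentration of melanin in a pure melanosome (100 vol.%),
#: consistent with the 2.14e-3 M per vol.% grid convention.
MELANOSOME_MOLAR = 0.214

#: Molar concentration of hemoglobin in whole blood (150 g/L, 44% hematocrit).
WHOLE_BLOOD_MOLAR = 2.32e-3


def load_chromophore_table(path=None) -> ChromophoreSpectra:
    """Load the packaged optical basis table as molar extinction spectra.

    The packaged table stores what the source literature actually
    tabulates: the melanosome absorption coefficient (cm^-1), the
    absorption coefficients of fully oxygenated and fully deoxygenated
    whole blood (cm^-1 at 150 g/L hemoglobin), the bilirubin molar
    extinction coefficient (cm^-1 M^-1), and the reduced scattering
    coefficient of skin.  The loader converts the absorption-coefficient
    columns to effective molar extinctions via ``eps = mua / (2.303 *
    C_pure)`` with the pure-phase molarities (melanosome 0.214 M, whole
    blood 2.32e-3 M), so that the ``mua = 2.303 * C * eps`` builders
    reproduce the tabulated coefficients exactly at 100 vol.%.

    Parameters
    ----------
    path
        Optional path to an alternative delimited table with columns
        ``wavelength_nm, mua_melanosome, mua_oxyblood, mua_deoxyblood,
        eps_bilirubin, musp``; when omitted the packaged default table
        is used.
    """
    import pandas as pd

    if path is None:
        ref = resources.files("dermospec").joinpath("data/chromophore_table.csv")
        with resources.as_file(ref) as p:
            raw = pd.read_csv(p, comment="#")
    else:
        raw = pd.read_csv(path, comment="#")
    return ChromophoreSpectra(
        wavelengths_nm=raw["wavelength_nm"].to_numpy(),
        eps_m=raw["mua_melanosome"].to_numpy() / (LN10 * MELANOSOME_MOLAR),
        eps_oh=raw["mua_oxyblood"].to_numpy() / (LN10 * WHOLE_BLOOD_MOLAR),
        eps_dh=raw["mua_deoxyblood"].to_numpy() / (LN10 * WHOLE_BLOOD_MOLAR),
        eps_bil=raw["eps_bilirubin"].to_numpy(),
        musp=raw["musp"].to_numpy(),
    )


@dataclass(frozen=True)
class ConcentrationSet:
    """A skin-model chromophore state.

    ``coh_volpct`` and ``cdh_volpct`` derive from total hemoglobin and
    oxygen saturation; their sum equals ``cth_volpct`` exactly by
    construction (``cdh = cth - coh``).
    """

    cm_volpct: float = 0.0
    cth_volpct: float = 0.0
    sto2_pct: float = 0.0
    cbil_mgdl: float = 0.0

    def __post_init__(self) -> None:
        if self.cm_volpct < 0:
            raise ValueError("melanin concentration must be >= 0")
        if self.cth_volpct < 0:
            raise ValueError("total hemoglobin concentration must be >= 0")
        if not 0.0 <= self.sto2_pct <= 100.0:
            raise ValueError("oxygen saturation must lie in [0, 100] %")
        if self.cbil_mgdl < 0:
            raise ValueError("bilirubin concentration must be >= 0")

    @property
    def coh_volpct(self) -> float:
        return self.cth_volpct * self.sto2_pct / 100.0

    @property
    def cdh_volpct(self) -> float:
        return self.cth_volpct - self.coh_volpct


@dataclass(frozen=True)
class UnitConventions:
    """Conversion factors between reported units and molar concentrations.

    The default hemoglobin factor equates 100 vol.% whole blood with
    2.32e-3 M hemoglobin (150 g/L at 44% hematocrit).  An alternative
    convention in circulation maps 0.2 vol.% to 4.65e-7 M (one-tenth of
    the default); it is available through :meth:`dilute_blood_convention`
    but is not the default because only the 150 g/L reading is
    consistent with standard whole-blood composition.

    ``f_bil`` is an empirical scaling of the bilirubin absorption term,
    accounting for the fraction of dermal bilirubin that is optically
    effective; it multiplies the bilirubin contribution to the dermal
    absorption coefficient.
    """

    melanin_molar_per_volpct: float = 2.14e-3
    hemoglobin_molar_per_volpct: float = 2.32e-5
    bilirubin_molar_mass: float = 584.67  # g/mol
    f_bil: float = 0.2

    def __post_init__(self) -> None:
        for name in ("melanin_molar_per_volpct", "hemoglobin_molar_per_volpct",
                     "bilirubin_molar_mass", "f_bil"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.f_bil > 1.0:
            raise ValueError("f_bil must lie in (0, 1]")

    @classmethod
    def dilute_blood_convention(cls) -> "UnitConventions":
        """Alternative convention: 0.2 vol.% whole blood = 4.65e-7 M hemoglobin."""
        return cls(hemoglobin_molar_per_volpct=4.65e-7 / 0.2)


@dataclass(frozen=True)
class MolarConcentrations:
    """Chromophore concentrations in mol/L."""

    cm_M: float
    coh_M: float
    cdh_M: float
    cbil_M: float


def concentrations_to_molar(
    c: ConcentrationSet, u: UnitConventions = UnitConventions()
) -> MolarConcentrations:
    """Convert a reported-unit concentration set to molar concentrations.

    Bilirubin in mg/dl converts via g/L (divide by 100) and the molar
    mass; hemoglobin and melanin scale linearly with their vol.% factors.
    """
    return MolarConcentrations(
        cm_M=c.cm_volpct * u.melanin_molar_per_volpct,
        coh_M=c.coh_volpct * u.hemoglobin_molar_per_volpct,
        cdh_M=c.cdh_volpct * u.hemoglobin_molar_per_volpct,
        cbil_M=(c.cbil_mgdl / 100.0) / u.bilirubin_molar_mass,
    )


def molar_to_concentrations(
    m: MolarConcentrations, u: UnitConventions = UnitConventions()
) -> ConcentrationSet:
    """Inverse of :func:`concentrations_to_molar` (exact round-trip)."""
    cth_M = m.coh_M + m.cdh_M
    cth_volpct = cth_M / u.hemoglobin_molar_per_volpct
    sto2 = 100.0 * m.coh_M / cth_M if cth_M > 0 else 0.0
    return ConcentrationSet(
        cm_volpct=m.cm_M / u.melanin_molar_per_volpct,
        cth_volpct=cth_volpct,
        sto2_pct=sto2,
        cbil_mgdl=m.cbil_M * u.bilirubin_molar_mass * 100.0,
    )


def epidermis_mua(
    c: ConcentrationSet,
    s: ChromophoreSpectra,
    u: UnitConventions = UnitConventions(),
) -> np.ndarray:
    """Epidermal absorption coefficient spectrum (cm^-1).

    Melanin is the only epidermal absorber in the model:
    ``mua = 2.303 * Cm[M] * eps_m``, exactly linear in the melanin
    concentration.
    """
    cm_M = c.cm_volpct * u.melanin_molar_per_volpct
    return LN10 * cm_M * s.eps_m


def dermis_mua(
    c: ConcentrationSet,
    s: ChromophoreSpectra,
    u: UnitConventions = UnitConventions(),
) -> np.ndarray:
    """Dermal absorption coefficient spectrum (cm^-1).

    Sum of oxy- and deoxyhemoglobin terms plus the f_bil-scaled
    bilirubin term; melanin does not contribute to the dermis.
    """
    m = concentrations_to_molar(c, u)
    return LN10 * (
        m.coh_M * s.eps_oh
        + m.cdh_M * s.eps_dh
        + u.f_bil * m.cbil_M * s.eps_bil
    )


def arteriovenous_oxygen_saturation(
    arterial_pct: float = 96.0,
    venous_pct: float = 60.0,
    venous_fraction: float = 0.75,
) -> float:
    """Volume-weighted oxygen saturation of mixed arteriovenous blood.

    Tissue oxygen saturation measured optically samples the full
    vascular bed.  With about 75% of blood volume in venules/veins and
    25% in arterioles/arteries, normal arterial saturation of 96% and
    venous saturation of 60% mix to 69% -- the expected resting skin
    value against which diffuse-reflectance StO2 readings are judged.
    """
    if not 0.0 <= venous_fraction <= 1.0:
        raise ValueError("venous_fraction must lie in [0, 1]")
    return venous_fraction * venous_pct + (1.0 - venous_fraction) * arterial_pct
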