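"""End-to-end estimation from measured spectra and hyperspectral cubes.

Measurements arrive either as single diffuse reflectance spectra
(two-column delimited text, or raw tissue/white-standard intensity
pairs) or as hyperspectral reflectance cubes (ENVI-style band-sequential
binary with a text header).  This module normalizes by the white
reference, resamples to the 14-point analysis grid, runs the stage-1
unmixing plus stage-2 prediction per spectrum or per pixel, and emits
concentration tables and maps.  No simulation happens at estimation
time: the conversion vectors are fitted once and reused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ChromophoreEstimate, ConversionVectors, predict
from .constants import ChromophoreSpectra
from .unmixing import (ReflectanceSpectrum, attenuation, design_matrix,
                       fit_attenuation)

__all__ = [
    "resample_to_grid",
    "estimate_spectrum",
    "HyperspectralCube",
    "ChromophoreMaps",
    "estimate_cube",
    "time_series",
    "read_spectrum",
    "write_spectrum",
    "read_envi_cube",
    "write_envi_cube",
]

#: Reflectance above this after white normalization is masked (specular glint).
DEFAULT_REFLECTANCE_CAP = 1.2

PLANE_NAMES = ("cm_volpct", "coh_volpct", "cdh_volpct", "cbil_mgdl",
               "cth_volpct", "sto2_pct")


def resample_to_grid(wavelengths_nm, values, target_nm) -> np.ndarray:
    """Linearly interpolate spectra onto the analysis grid.

    ``values`` may be a 1-D spectrum or an array whose last axis is the
    band axis.  When the target grid is an exact subset of the input
    bands the matching samples are selected without interpolation.

    Raises
    ------
    ValueError
        If the input bands do not cover the full target range.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    target = np.asarray(target_nm, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("input bands must be strictly increasing")
    if values.shape[-1] != wl.size:
        raise ValueError("band axis of values must match the wavelength list")
    lo, hi = target.min(), target.max()
    if wl.min() > lo or wl.max() < hi:
        raise ValueError(
            f"input bands span [{wl.min():g}, {wl.max():g}] nm and do not "
            f"cover the required [{lo:g}, {hi:g}] nm")
    # exact subset: pure selection, bit-identical values
    idx = np.searchsorted(wl, target)
    idx = np.clip(idx, 0, wl.size - 1)
    if np.array_equal(wl[idx], target):
        return values[..., idx]
    flat = values.reshape(-1, wl.size)
    out = np.empty((flat.shape[0], target.size))
    for i, row in enumerate(flat):
        out[i] = np.interp(target, wl, row)
    return out.reshape(values.shape[:-1] + (target.size,))


def estimate_spectrum(
    r: ReflectanceSpectrum,
    b: ConversionVectors,
    s: ChromophoreSpectra,
    clip: bool = False,
) -> ChromophoreEstimate:
    """Estimate chromophore concentrations from one reflectance spectrum.

    Resamples onto the basis grid if needed, converts to attenuation,
    fits the stage-1 regression, and applies the conversion vectors.
    Refuses vectors calibrated against a different extinction table.
    """
    if b.table_version and b.table_version != s.version:
        raise ValueError(
            "conversion vectors were calibrated against a different "
            f"extinction table (vectors: {b.table_version}, "
            f"loaded: {s.version})")
    values = r.r
    if r.wavelengths_nm.size != s.n_bands or not np.allclose(
            r.wavelengths_nm, s.wavelengths_nm):
        values = resample_to_grid(r.wavelengths_nm, r.r, s.wavelengths_nm)
        r = ReflectanceSpectrum(wavelengths_nm=s.wavelengths_nm, r=values)
    coeffs = fit_attenuation(attenuation(r), s)
    return predict(coeffs, b, clip=clip)


@dataclass(frozen=True)
class HyperspectralCube:
    """(rows, cols, bands) raster with per-band wavelengths in nm."""

    data: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if data.ndim != 3:
            raise ValueError("cube must be 3-D (rows, cols, bands)")
        if wl.ndim != 1 or wl.size != data.shape[2]:
            raise ValueError("band wavelengths must match the cube band axis")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("band wavelengths must be strictly increasing")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "wavelengths_nm", wl)

    @property
    def shape(self):
        return self.data.shape


@dataclass(frozen=True)
class ChromophoreMaps:
    """Per-pixel concentration planes plus a validity mask.

    ``mask`` is True where the pixel was estimated; masked-out pixels
    are NaN in every plane.
    """

    planes: dict
    mask: np.ndarray

    def __post_init__(self) -> None:
        for name in PLANE_NAMES:
            if name not in self.planes:
                raise ValueError(f"missing plane {name}")
            if self.planes[name].shape != self.mask.shape:
                raise ValueError("plane and mask dimensions differ")

    def summary(self, roi: np.ndarray | None = None) -> pd.DataFrame:
        """Per-plane mean/std over valid pixels (optionally within a ROI)."""
        sel = self.mask if roi is None else (self.mask & roi)
        rows = []
        for name in PLANE_NAMES:
            vals = self.planes[name][sel]
            rows.append({"plane": name,
                         "mean": float(np.nanmean(vals)) if vals.size else np.nan,
                         "std": float(np.nanstd(vals)) if vals.size else np.nan,
                         "n_pixels": int(vals.size)})
        return pd.DataFrame(rows)


def _normalize_cube(cube: HyperspectralCube, white) -> np.ndarray:
    """Per-pixel reflectance from raw intensities and a white reference.

    ``white`` may be None (cube already holds reflectance), a 1-D
    spectrum applied globally, or a full cube for per-pixel referencing.
    """
    if white is None:
        return cube.data
    if isinstance(white, HyperspectralCube):
        if white.data.shape != cube.data.shape:
            raise ValueError("white-reference cube dimensions differ from cube")
        wdata = white.data
    else:
        wdata = np.asarray(white, dtype=float)
        if wdata.ndim != 1 or wdata.size != cube.data.shape[2]:
            raise ValueError("white-reference spectrum must match the band axis")
        wdata = wdata[None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(wdata > 0, cube.data / wdata, -1.0)


def estimate_cube(
    cube: HyperspectralCube,
    white,
    b: ConversionVectors,
    s: ChromophoreSpectra,
    clip: bool = False,
    reflectance_cap: float = DEFAULT_REFLECTANCE_CAP,
) -> ChromophoreMaps:
    """Per-pixel chromophore estimation over a hyperspectral cube.

    Pixels whose reflectance is non-positive or above ``reflectance_cap``
    at any analysis wavelength are masked, not guessed.  The stage-1
    fit is solved for all valid pixels in one batched least-squares.
    """
    if b.table_version and b.table_version != s.version:
        raise ValueError("conversion vectors/table version mismatch")
    refl = _normalize_cube(cube, white)
    refl = resample_to_grid(cube.wavelengths_nm, refl, s.wavelengths_nm)
    rows, cols, nb = refl.shape
    flat = refl.reshape(-1, nb)
    valid = np.all((flat > 0) & np.isfinite(flat), axis=1)
    over = valid & np.any(flat > reflectance_cap, axis=1)
    if over.any():
        warnings.warn(f"{int(over.sum())} pixels exceed the reflectance cap "
                      f"{reflectance_cap} and were masked", stacklevel=2)
        valid &= ~over
    if not valid.any():
        warnings.warn("all pixels masked; no estimates produced", stacklevel=2)

    planes = {name: np.full(rows * cols, np.nan) for name in PLANE_NAMES}
    if valid.any():
        A = -np.log10(flat[valid])  # (n_valid, bands)
        X = design_matrix(s)
        beta, _, _, _ = np.linalg.lstsq(X, A.T, rcond=None)  # (5, n_valid)
        avec = np.vstack([np.ones(beta.shape[1]), beta])  # (6, n_valid)
        B = np.vstack([b.b_m, b.b_oh, b.b_dh, b.b_bil])  # (4, 6)
        conc = B @ avec  # (4, n_valid)
        if clip:
            conc = np.maximum(conc, 0.0)
        cm, coh, cdh, cbil = conc
        cth = coh + cdh
        with np.errstate(divide="ignore", invalid="ignore"):
            sto2 = np.where(cth > 0, 100.0 * coh / cth, np.nan)
        for name, vals in zip(PLANE_NAMES, (cm, coh, cdh, cbil, cth, sto2)):
            planes[name][valid] = vals
    return ChromophoreMaps(
        planes={k: v.reshape(rows, cols) for k, v in planes.items()},
        mask=valid.reshape(rows, cols))


def time_series(
    records,
    b: ConversionVectors,
    s: ChromophoreSpectra,
    clip: bool = False,
) -> pd.DataFrame:
    """Estimate a timestamped sequence of spectra.

    ``records`` is an iterable of (timestamp, ReflectanceSpectrum)
    pairs with non-decreasing timestamps.  Returns one estimate row per
    record in input order; an empty input yields an empty table.
    """
    records = list(records)
    cols = ["timestamp", *PLANE_NAMES]
    if not records:
        return pd.DataFrame(columns=cols)
    times = [t for t, _ in records]
    if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("timestamps must be non-decreasing")
    if any(t1 == t0 for t0, t1 in zip(times, times[1:])):
        warnings.warn("duplicate timestamps present; all records kept",
                      stacklevel=2)
    rows = []
    for t, r in records:
        est = estimate_spectrum(r, b, s, clip=clip)
        rows.append({"timestamp": t, "cm_volpct": est.cm_volpct,
                     "coh_volpct": est.coh_volpct,
                     "cdh_volpct": est.cdh_volpct,
                     "cbil_mgdl": est.cbil_mgdl,
                     "cth_volpct": est.cth_volpct,
                     "sto2_pct": est.sto2_pct})
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# text and ENVI I/O


def read_spectrum(path) -> ReflectanceSpectrum:
    """Read a two-column delimited spectrum (wavelength nm, reflectance)."""
    arr = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError("spectrum file must have two columns")
    return ReflectanceSpectrum(wavelengths_nm=arr[:, 0], r=arr[:, 1])


def write_spectrum(path, spectrum: ReflectanceSpectrum, header: str = "") -> None:
    """Write a spectrum as two-column text with an optional comment header."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# wavelength_nm reflectance\n")
        for wl, r in zip(spectrum.wavelengths_nm, spectrum.r):
            fh.write(f"{wl:.1f} {r:.10g}\n")


def write_envi_cube(path_stem, cube: HyperspectralCube) -> tuple:
    """Write a cube as ENVI band-sequential float32 raster plus header.

    Returns (data_path, header_path).  ``path_stem`` gets ``.raw`` and
    ``.hdr`` suffixes.
    """
    data_path = str(path_stem) + ".raw"
    hdr_path = str(path_stem) + ".hdr"
    rows, cols, bands = cube.shape
    bsq = np.ascontiguousarray(np.moveaxis(cube.data, 2, 0).astype("<f4"))
    bsq.tofile(data_path)
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths_nm)
    with open(hdr_path, "w") as fh:
        fh.write("ENVI\n")
        fh.write(f"samples = {cols}\n")
        fh.write(f"lines = {rows}\n")
        fh.write(f"bands = {bands}\n")
        fh.write("header offset = 0\n")
        fh.write("data type = 4\n")
        fh.write("interleave = bsq\n")
        fh.write("byte order = 0\n")
        fh.write("wavelength units = Nanometers\n")
        fh.write("wavelength = {" + wl + "}\n")
    return data_path, hdr_path


def _parse_envi_header(hdr_path) -> dict:
    text = open(hdr_path).read()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header")
    fields = {}
    key = None
    buf = ""
    for line in text.splitlines()[1:]:
        if "=" in line and key is None:
            k, v = line.split("=", 1)
            k = k.strip().lower()
            v = v.strip()
            if v.startswith("{") and "}" not in v:
                key, buf = k, v
            else:
                fields[k] = v.strip("{}").strip()
        elif key is not None:
            buf += " " + line.strip()
            if "}" in line:
                fields[key] = buf.strip("{}").strip(" {}")
                key = None
    return fields


_ENVI_DTYPES = {"1": "u1", "2": "<i2", "3": "<i4", "4": "<f4",
                "5": "<f8", "12": "<u2"}


def read_envi_cube(hdr_path, data_path=None) -> HyperspectralCube:
    """Read an ENVI header + raw raster into a cube.

    Supports BSQ, BIL and BIP interleaves.  The header must carry the
    band wavelengths: band positions are never guessed.
    """
    fields = _parse_envi_header(hdr_path)
    if "wavelength" not in fields:
        raise ValueError("ENVI header lacks band wavelengths")
    wl = np.array([float(w) for w in fields["wavelength"].split(",")])
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _ENVI_DTYPES[fields.get("data type", "4")]
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", "0"))
    if data_path is None:
        stem = str(hdr_path)
        stem = stem[:-4] if stem.endswith(".hdr") else stem
        data_path = stem + ".raw"
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    if raw.size != rows * cols * bands:
        raise ValueError("raster size does not match header dimensions")
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return HyperspectralCube(data=data.astype(float), wavelengths_nm=wl)
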