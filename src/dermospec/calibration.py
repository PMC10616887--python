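"""Stage-2 calibration: conversion vectors from coefficients to concentrations.

The stage-1 regression coefficients mix concentration with mean optical
path length, which itself depends on every chromophore, so no single
coefficient maps to a single concentration.  The calibration therefore
fits, on a simulated training set spanning the physiological grid, four
linear conversion vectors b such that

    Cm   = b_m  . a,    Coh = b_oh . a,
    Cdh  = b_dh . a,    Cbil = b_bil . a,

with a = (1, am, aoh, adh, abil, a0).  The training grid is the full
cross of melanin 1-10 vol.%, bilirubin {0, 1, 5, 10, 15, 20} mg/dl,
total hemoglobin {0.2, 0.4, 0.6, 0.8, 1.0} vol.% and oxygen saturation
{0, 20, 40, 60, 80, 100}% -- 1800 combinations.  The vectors are fitted
once; estimation afterwards never touches the simulator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ChromophoreSpectra, ConcentrationSet, UnitConventions
from .mc import MCConfig, sweep_grid
from .unmixing import (AttenuationSpectrum, RegressionCoefficients,
                       ReflectanceSpectrum, attenuation, fit_attenuation)

__all__ = [
    "TRAINING_LEVELS",
    "training_grid",
    "TrainingSet",
    "build_training_set",
    "ConversionVectors",
    "fit_conversion_vectors",
    "ChromophoreEstimate",
    "predict",
]

#: Concentration levels of the calibration grid (full cross = 1800 rows).
TRAINING_LEVELS = {
    "cm_volpct": (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0),
    "cbil_mgdl": (0.0, 1.0, 5.0, 10.0, 15.0, 20.0),
    "cth_volpct": (0.2, 0.4, 0.6, 0.8, 1.0),
    "sto2_pct": (0.0, 20.0, 40.0, 60.0, 80.0, 100.0),
}

_COEF_COLUMNS = ("am", "aoh", "adh", "abil", "a0")
_TARGET_COLUMNS = ("cm_volpct", "coh_volpct", "cdh_volpct", "cbil_mgdl")


def _thin(levels):
    return tuple(levels[::2])


def training_grid(thin: bool = False):
    """The calibration concentration grid as a list of states.

    ``thin=True`` keeps every other level of each factor (desk-scale
    fast mode), reducing 1800 rows to 135.
    """
    lv = {k: (_thin(v) if thin else v) for k, v in TRAINING_LEVELS.items()}
    return [
        ConcentrationSet(cm_volpct=cm, cth_volpct=cth, sto2_pct=sto2,
                         cbil_mgdl=cbil)
        for cm in lv["cm_volpct"]
        for cbil in lv["cbil_mgdl"]
        for cth in lv["cth_volpct"]
        for sto2 in lv["sto2_pct"]
    ]


@dataclass(frozen=True)
class TrainingSet:
    """Given concentrations paired with fitted stage-1 coefficients.

    ``frame`` has one row per grid combination with the concentration
    columns, the reflectance columns from the sweep, and the coefficient
    columns am, aoh, adh, abil, a0.
    """

    frame: pd.DataFrame
    table_version: str
    n_photons: int
    seed: int

    def __post_init__(self) -> None:
        missing = [c for c in _COEF_COLUMNS + _TARGET_COLUMNS
                   if c not in self.frame.columns]
        if missing:
            raise ValueError(f"training set missing columns: {missing}")
        if self.frame[list(_COEF_COLUMNS)].isna().any().any():
            raise ValueError("training set contains missing coefficients")

    def coefficient_matrix(self) -> np.ndarray:
        """Design matrix with columns (1, am, aoh, adh, abil, a0)."""
        a = self.frame[list(_COEF_COLUMNS)].to_numpy()
        return np.column_stack([np.ones(len(a)), a])


def build_training_set(
    grid,
    spectra: ChromophoreSpectra,
    cfg: MCConfig = MCConfig(),
    units: UnitConventions = UnitConventions(),
    g: float = 0.0,
    method: str = "analog",
) -> TrainingSet:
    """Simulate the grid and unmix every spectrum.

    Runs the forward model for each combination, converts each
    reflectance spectrum to attenuation, and fits the stage-1 regression,
    producing one coefficient row per combination.  Deterministic for a
    fixed seed.
    """
    frame = sweep_grid(grid, spectra, cfg, units, g=g, method=method)
    rd_cols = [f"rd_{int(w)}" for w in spectra.wavelengths_nm]
    coeffs = []
    for rd in frame[rd_cols].to_numpy():
        r = ReflectanceSpectrum(wavelengths_nm=spectra.wavelengths_nm, r=rd)
        fit = fit_attenuation(attenuation(r), spectra)
        coeffs.append([fit.am, fit.aoh, fit.adh, fit.abil, fit.a0])
    frame[list(_COEF_COLUMNS)] = np.asarray(coeffs)
    return TrainingSet(frame=frame, table_version=spectra.version,
                       n_photons=cfg.n_photons, seed=cfg.seed)


@dataclass(frozen=True)
class ConversionVectors:
    """The four fitted 6-vectors mapping a = (1, am, aoh, adh, abil, a0)
    to concentrations, with training diagnostics and provenance."""

    b_m: np.ndarray
    b_oh: np.ndarray
    b_dh: np.ndarray
    b_bil: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    table_version: str = ""
    n_photons: int = 0
    seed: int = 0
    grid_hash: str = ""

    def __post_init__(self) -> None:
        for name in ("b_m", "b_oh", "b_dh", "b_bil"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (6,):
                raise ValueError(f"{name} must have exactly six entries")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite entries")
            object.__setattr__(self, name, v)

    def save(self, path) -> None:
        """Serialize to a small JSON text file with provenance metadata."""
        payload = {
            "b_m": self.b_m.tolist(), "b_oh": self.b_oh.tolist(),
            "b_dh": self.b_dh.tolist(), "b_bil": self.b_bil.tolist(),
            "diagnostics": self.diagnostics,
            "table_version": self.table_version,
            "n_photons": self.n_photons, "seed": self.seed,
            "grid_hash": self.grid_hash,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ConversionVectors":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            b_m=np.asarray(payload["b_m"]), b_oh=np.asarray(payload["b_oh"]),
            b_dh=np.asarray(payload["b_dh"]),
            b_bil=np.asarray(payload["b_bil"]),
            diagnostics=payload.get("diagnostics", {}),
            table_version=payload.get("table_version", ""),
            n_photons=payload.get("n_photons", 0),
            seed=payload.get("seed", 0),
            grid_hash=payload.get("grid_hash", ""),
        )


def _grid_hash(frame: pd.DataFrame) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(
        frame[list(_TARGET_COLUMNS)].to_numpy()).tobytes())
    return "sha256:" + h.hexdigest()[:16]


def fit_conversion_vectors(ts: TrainingSet) -> ConversionVectors:
    """Fit the four conversion vectors by ordinary least squares.

    Each target concentration (melanin and both hemoglobin species in
    vol.%, bilirubin in mg/dl) is regressed independently on the
    coefficient design (1, am, aoh, adh, abil, a0).  Requires at least
    seven rows and a full-rank design.
    """
    X = ts.coefficient_matrix()
    if X.shape[0] < 7:
        raise ValueError("need at least 7 training rows to fit 6 coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        stds = X.std(axis=0)
        raise ValueError(
            f"rank-deficient coefficient design (rank {rank} of "
            f"{X.shape[1]}); column stds: {np.round(stds, 6).tolist()}")
    vectors = {}
    diagnostics = {}
    for name, target in zip(("b_m", "b_oh", "b_dh", "b_bil"), _TARGET_COLUMNS):
        y = ts.frame[target].to_numpy()
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ beta
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        vectors[name] = beta
        diagnostics[target] = {
            "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
            "rmse": float(np.sqrt(ss_res / len(y))),
        }
    return ConversionVectors(
        **vectors, diagnostics=diagnostics, table_version=ts.table_version,
        n_photons=ts.n_photons, seed=ts.seed, grid_hash=_grid_hash(ts.frame))


@dataclass(frozen=True)
class ChromophoreEstimate:
    """Concentrations predicted from one spectrum.

    Raw values may be negative (out-of-range spectra); ``clipped()``
    returns a non-negative copy.  ``sto2_pct`` is NaN with
    ``sto2_defined`` False when total hemoglobin is non-positive.
    """

    cm_volpct: float
    coh_volpct: float
    cdh_volpct: float
    cbil_mgdl: float

    @property
    def cth_volpct(self) -> float:
        return self.coh_volpct + self.cdh_volpct

    @property
    def sto2_defined(self) -> bool:
        return self.cth_volpct > 0

    @property
    def sto2_pct(self) -> float:
        if not self.sto2_defined:
            return float("nan")
        return 100.0 * self.coh_volpct / self.cth_volpct

    def clipped(self) -> "ChromophoreEstimate":
        return ChromophoreEstimate(
            cm_volpct=max(self.cm_volpct, 0.0),
            coh_volpct=max(self.coh_volpct, 0.0),
            cdh_volpct=max(self.cdh_volpct, 0.0),
            cbil_mgdl=max(self.cbil_mgdl, 0.0),
        )


def predict(a: RegressionCoefficients, b: ConversionVectors,
            clip: bool = False) -> ChromophoreEstimate:
    """Apply the conversion vectors to one coefficient vector."""
    vec = a.as_vector()
    est = ChromophoreEstimate(
        cm_volpct=float(b.b_m @ vec),
        coh_volpct=float(b.b_oh @ vec),
        cdh_volpct=float(b.b_dh @ vec),
        cbil_mgdl=float(b.b_bil @ vec),
    )
    return est.clipped() if clip else est
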