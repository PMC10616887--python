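"""In-silico validation: synthetic spectra, recovery and coefficient studies.

Two scripted experiments assess the calibrated inversion without any
measured data:

* the *recovery* study trains the conversion vectors on the full
  calibration grid, independently simulates a 300-combination
  validation grid (oxygen saturation fixed at 60%, fresh seeds), and
  compares estimated with given concentrations;
* the *coefficient* study sweeps one concentration at a time and records
  how each stage-1 coefficient responds -- melanin's coefficient should
  grow monotonically with melanin, while the intercept should be nearly
  flat in bilirubin.

The same forward model doubles as the package's fixture factory for
spectra files and synthetic hyperspectral cubes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import (ConversionVectors, TrainingSet, build_training_set,
                          fit_conversion_vectors, predict, training_grid)
from .constants import ChromophoreSpectra, ConcentrationSet, UnitConventions
from .mc import MCConfig, simulate_reflectance, skin_model, sweep_grid
from .pipeline import HyperspectralCube, write_envi_cube, write_spectrum
from .unmixing import ReflectanceSpectrum, attenuation, fit_attenuation

__all__ = [
    "validation_grid",
    "ValidationReport",
    "run_recovery_experiment",
    "coefficient_curves",
    "curves_from_training_set",
    "make_fixture_spectra",
    "make_two_region_cube",
]

RECOVERY_TARGETS = ("cm_volpct", "coh_volpct", "cdh_volpct", "cbil_mgdl",
                    "cth_volpct")

VALIDATION_STO2_PCT = 60.0


def validation_grid(thin: bool = False):
    """The held-out grid: full melanin x hemoglobin x bilirubin cross at
    60% oxygen saturation (300 combinations; 45 when thinned)."""
    grid = training_grid(thin=thin)
    seen = set()
    out = []
    for c in grid:
        key = (c.cm_volpct, c.cth_volpct, c.cbil_mgdl)
        if key not in seen:
            seen.add(key)
            out.append(replace(c, sto2_pct=VALIDATION_STO2_PCT))
    return out


@dataclass(frozen=True)
class ValidationReport:
    """Given-vs-estimated comparison of one recovery run.

    ``pairs`` has the given concentration columns and ``est_*`` columns,
    one row per validation combination.  Correlation, bias and RMSE are
    per target; provenance records grids, photon counts and seeds.
    """

    pairs: pd.DataFrame
    correlations: dict
    bias: dict
    rmse: dict
    vectors: ConversionVectors
    training_frame: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [{"target": t, "pearson_r": self.correlations[t],
                 "bias": self.bias[t], "rmse": self.rmse[t]}
                for t in RECOVERY_TARGETS]
        return pd.DataFrame(rows)


def estimate_training_frame(frame: pd.DataFrame,
                            vectors: ConversionVectors) -> pd.DataFrame:
    """Apply fitted vectors to the coefficient rows of a sweep frame."""
    out = frame.copy()
    X = np.column_stack([np.ones(len(frame)),
                         frame[["am", "aoh", "adh", "abil", "a0"]].to_numpy()])
    for name, b in (("cm_volpct", vectors.b_m), ("coh_volpct", vectors.b_oh),
                    ("cdh_volpct", vectors.b_dh), ("cbil_mgdl", vectors.b_bil)):
        out[f"est_{name}"] = X @ b
    out["est_cth_volpct"] = out["est_coh_volpct"] + out["est_cdh_volpct"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["est_sto2_pct"] = np.where(
            out["est_cth_volpct"] > 0,
            100.0 * out["est_coh_volpct"] / out["est_cth_volpct"], np.nan)
    return out


#: Study-scale photon count per wavelength for the recovery experiment.
FULL_SCALE_PHOTONS = 5_000_000


def run_recovery_experiment(
    spectra: ChromophoreSpectra,
    units: UnitConventions = UnitConventions(),
    train_cfg: MCConfig | None = None,
    val_cfg: MCConfig | None = None,
    thin: bool = False,
    method: str = "pathlength",
) -> ValidationReport:
    """Train the conversion vectors, then estimate an independent grid.

    Training uses the calibration grid; validation simulates the
    60%-saturation grid with its own seed stream so recovery is
    out-of-sample with respect to Monte Carlo noise.  Seeds must differ
    between the two configurations.

    Defaults run the study conditions: full grids at 5e6 photons per
    wavelength, feasible on one CPU because the sweep uses path-length
    reweighting (the hemoglobin signature in the spectra is weak, so the
    inversion genuinely needs full photon statistics).
    """
    if train_cfg is None:
        train_cfg = MCConfig(n_photons=FULL_SCALE_PHOTONS, seed=11)
    if val_cfg is None:
        val_cfg = MCConfig(n_photons=FULL_SCALE_PHOTONS, seed=202)
    if train_cfg.seed == val_cfg.seed:
        raise ValueError("training and validation seeds must be disjoint")
    ts = build_training_set(training_grid(thin=thin), spectra, train_cfg,
                            units, method=method)
    vectors = fit_conversion_vectors(ts)
    val_ts = build_training_set(validation_grid(thin=thin), spectra,
                                val_cfg, units, method=method)
    pairs = estimate_training_frame(val_ts.frame, vectors)
    correlations, bias, rmse = {}, {}, {}
    for t in RECOVERY_TARGETS:
        given = pairs[t].to_numpy()
        est = pairs[f"est_{t}"].to_numpy()
        correlations[t] = float(stats.pearsonr(given, est).statistic)
        bias[t] = float(np.mean(est - given))
        rmse[t] = float(np.sqrt(np.mean((est - given) ** 2)))
    return ValidationReport(
        pairs=pairs, correlations=correlations, bias=bias, rmse=rmse,
        vectors=vectors, training_frame=ts.frame,
        provenance={
            "train_seed": train_cfg.seed, "val_seed": val_cfg.seed,
            "train_photons": train_cfg.n_photons,
            "val_photons": val_cfg.n_photons,
            "n_train": len(ts.frame), "n_val": len(pairs),
            "thin": thin, "method": method,
            "table_version": spectra.version,
        })


def coefficient_curves(
    spectra: ChromophoreSpectra,
    vary: str,
    levels,
    fixed: dict,
    cfg: MCConfig = MCConfig(),
    units: UnitConventions = UnitConventions(),
    method: str = "analog",
) -> pd.DataFrame:
    """Simulate a one-factor sweep and record the stage-1 coefficients.

    ``vary`` is one of the ConcentrationSet fields (``cm_volpct``,
    ``cth_volpct``, ``sto2_pct``, ``cbil_mgdl``); ``fixed`` supplies the
    remaining fields.  Returns one row per level with the coefficient
    columns.
    """
    grid = [ConcentrationSet(**{**fixed, vary: float(level)})
            for level in levels]
    ts = build_training_set(grid, spectra, cfg, units, method=method)
    cols = [vary, "cm_volpct", "cth_volpct", "sto2_pct", "cbil_mgdl",
            "coh_volpct", "cdh_volpct", "am", "aoh", "adh", "abil", "a0"]
    cols = list(dict.fromkeys(cols))
    return ts.frame[cols]


def curves_from_training_set(frame: pd.DataFrame, vary: str,
                             fixed: dict) -> pd.DataFrame:
    """Extract a one-factor coefficient curve from an existing sweep frame."""
    sel = np.ones(len(frame), dtype=bool)
    for k, v in fixed.items():
        sel &= np.isclose(frame[k].to_numpy(), v)
    out = frame.loc[sel].sort_values(vary).reset_index(drop=True)
    if out.empty:
        raise ValueError("no rows match the requested slice")
    return out


def normalized_slope(x, y) -> float:
    """Least-squares slope of y against x rescaled to [0, 1].

    Puts slopes taken against different concentration axes on a common
    footing so their magnitudes can be compared.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        raise ValueError("slice must vary the concentration")
    xn = (x - x.min()) / span
    return float(np.polyfit(xn, y, 1)[0])


def make_fixture_spectra(
    grid,
    spectra: ChromophoreSpectra,
    cfg: MCConfig = MCConfig(),
    units: UnitConventions = UnitConventions(),
    outdir=None,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Forward-simulate spectra and (optionally) write them with a manifest.

    Returns the ground-truth table; when ``outdir`` is given, writes one
    two-column spectrum file per combination plus ``truth.csv`` and a
    JSON manifest recording seed, photon count and table version.
    Deterministic per seed: same seed, byte-identical files.

    ``noise_sd`` optionally applies multiplicative Gaussian noise
    (relative standard deviation) on top of the Monte Carlo shot noise;
    it is off by default since no measurement-noise model is part of the
    study design.
    """
    frame = sweep_grid(grid, spectra, cfg, units)
    if noise_sd > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence(
            cfg.seed, spawn_key=(0xF1,)))
        rd_cols = [f"rd_{int(w)}" for w in spectra.wavelengths_nm]
        vals = frame[rd_cols].to_numpy()
        frame[rd_cols] = vals * rng.normal(1.0, noise_sd, size=vals.shape)
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rd_cols = [f"rd_{int(w)}" for w in spectra.wavelengths_nm]
        names = []
        for i, row in frame.iterrows():
            name = f"spectrum_{i:04d}.txt"
            sp = ReflectanceSpectrum(wavelengths_nm=spectra.wavelengths_nm,
                                     r=row[rd_cols].to_numpy())
            write_spectrum(
                outdir / name, sp,
                header=(f"synthetic forward-model spectrum; seed={cfg.seed} "
                        f"photons={cfg.n_photons}"))
            names.append(name)
        truth = frame.drop(columns=[c for c in frame.columns
                                    if c.startswith("se_")])
        truth.insert(0, "file", names)
        truth.to_csv(outdir / "truth.csv", index=False)
        manifest = {
            "seed": cfg.seed, "n_photons": cfg.n_photons,
            "table_version": spectra.version, "n_spectra": len(frame),
            "files": names,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return frame


def make_two_region_cube(
    left: ConcentrationSet,
    right: ConcentrationSet,
    spectra: ChromophoreSpectra,
    shape=(8, 8),
    cfg: MCConfig = MCConfig(),
    units: UnitConventions = UnitConventions(),
) -> tuple:
    """Synthetic two-region hyperspectral cube for map tests.

    The left half of the image carries the forward-model spectrum of
    ``left`` and the right half that of ``right``.  Returns
    (HyperspectralCube, truth dict with the two spectra).
    """
    rows, cols = shape
    res_l = simulate_reflectance(skin_model(left, spectra, units), cfg)
    res_r = simulate_reflectance(skin_model(right, spectra, units),
                                 replace(cfg, seed=cfg.seed + 1))
    data = np.empty((rows, cols, spectra.n_bands))
    half = cols // 2
    data[:, :half, :] = res_l.reflectance
    data[:, half:, :] = res_r.reflectance
    cube = HyperspectralCube(data=data, wavelengths_nm=spectra.wavelengths_nm)
    truth = {"left": res_l.reflectance, "right": res_r.reflectance,
             "split_col": half}
    return cube, truth
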