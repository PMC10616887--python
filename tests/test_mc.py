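import numpy as np
import pytest

from dermospec import (ConcentrationSet, Layer, MCConfig, TissueModel,
                       simulate_reflectance, skin_model, specular_reflectance,
                       sweep_grid)


def single_layer(mua, mus, thickness, n=1.0, nb=1, g=0.0):
    return TissueModel(
        layers=(Layer(thickness_cm=thickness, refractive_index=n,
                      mua=np.full(nb, float(mua)), mus=np.full(nb, float(mus)),
                      g=g),),
        wavelengths_nm=np.arange(500.0, 500.0 + 10 * nb, 10.0))


class TestSpecular:
    def test_matched_indices_no_reflection(self):
        assert specular_reflectance(1.0, 1.0) == 0.0

    def test_air_tissue_value(self):
        assert specular_reflectance(1.0, 1.4) == pytest.approx(
            (0.4 / 2.4) ** 2)

    def test_symmetric(self):
        assert specular_reflectance(1.0, 1.4) == specular_reflectance(1.4, 1.0)


class TestEnergyBookkeeping:
    def test_conservation_identity_on_skin_model(self, spectra):
        c = ConcentrationSet(cm_volpct=5, cth_volpct=0.6, sto2_pct=60,
                             cbil_mgdl=10)
        res = simulate_reflectance(skin_model(c, spectra),
                                   MCConfig(n_photons=3000, seed=4))
        assert np.all(res.conservation_error < 1e-6)

    def test_no_absorber_all_weight_reflected_or_transmitted(self):
        model = single_layer(mua=0.0, mus=100.0, thickness=10.0)
        res = simulate_reflectance(model, MCConfig(n_photons=3000, seed=1))
        # with no absorption the weight never drops: exact identity
        assert res.absorbed[0] == 0.0
        assert res.rd[0] + res.transmitted[0] == pytest.approx(1.0, abs=1e-12)

    def test_pure_absorber_never_returns_photons(self):
        model = single_layer(mua=10.0, mus=0.0, thickness=1.0)
        res = simulate_reflectance(model, MCConfig(n_photons=5000, seed=2))
        assert res.rd[0] == 0.0


class TestTransportOracles:
    def test_beer_lambert_transmission_of_clear_absorber(self):
        # non-scattering slab, matched boundaries: T = exp(-mua*d)
        mua, d, n = 3.0, 0.5, 100_000
        model = single_layer(mua=mua, mus=0.0, thickness=d)
        res = simulate_reflectance(model, MCConfig(n_photons=n, seed=3))
        expected = np.exp(-mua * d)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(res.transmitted[0] - expected) < 3 * se

    def test_thick_nonabsorbing_scatterer_reflects_everything(self):
        # mus*d = 500 transport mean free paths, matched boundaries
        model = single_layer(mua=0.0, mus=100.0, thickness=5.0)
        res = simulate_reflectance(model, MCConfig(n_photons=10_000, seed=5))
        assert res.rd[0] > 0.99

    def test_reflectance_decreases_with_absorption(self, spectra):
        # paired seeds: same photon paths, higher dermal absorption
        lo = ConcentrationSet(cm_volpct=3, cth_volpct=0.2, sto2_pct=60)
        hi = ConcentrationSet(cm_volpct=3, cth_volpct=1.0, sto2_pct=60)
        cfg = MCConfig(n_photons=20_000, seed=6)
        r_lo = simulate_reflectance(skin_model(lo, spectra), cfg)
        r_hi = simulate_reflectance(skin_model(hi, spectra), cfg)
        tol = 3 * np.sqrt(r_lo.rd_se ** 2 + r_hi.rd_se ** 2)
        assert np.all(r_hi.rd <= r_lo.rd + tol)

    def test_similarity_relation_anisotropic_vs_isotropic(self, spectra, units):
        # g=0 with mus=musp matches g=0.9 with mus=musp/(1-g) in the
        # diffusion regime (2% relative on the two-layer skin model)
        c = ConcentrationSet(cm_volpct=3, cth_volpct=0.6, sto2_pct=60,
                             cbil_mgdl=5)
        sub = slice(9, 11)  # 550 and 560 nm: diffuse, high-reflectance bands

        import dataclasses

        small = dataclasses.replace(
            spectra,
            wavelengths_nm=spectra.wavelengths_nm[sub],
            eps_m=spectra.eps_m[sub], eps_oh=spectra.eps_oh[sub],
            eps_dh=spectra.eps_dh[sub], eps_bil=spectra.eps_bil[sub],
            musp=spectra.musp[sub], version="sub")
        iso = simulate_reflectance(skin_model(c, small, units, g=0.0),
                                   MCConfig(n_photons=100_000, seed=7))
        aniso = simulate_reflectance(skin_model(c, small, units, g=0.9),
                                     MCConfig(n_photons=50_000, seed=8))
        rel = np.abs(aniso.rd - iso.rd) / iso.rd
        assert np.all(rel < 0.02)


class TestSweepGrid:
    def test_single_combination_single_row(self, spectra):
        df = sweep_grid([ConcentrationSet(cm_volpct=5, cth_volpct=0.6,
                                          sto2_pct=60)],
                        spectra, MCConfig(n_photons=1000, seed=9))
        assert len(df) == 1
        assert sum(c.startswith("rd_") for c in df.columns) == 14

    @pytest.mark.parametrize("method", ["analog", "pathlength"])
    def test_repeat_runs_bit_identical(self, spectra, method):
        grid = [ConcentrationSet(cm_volpct=2, cth_volpct=0.4, sto2_pct=40),
                ConcentrationSet(cm_volpct=8, cth_volpct=0.8, sto2_pct=80,
                                 cbil_mgdl=15)]
        cfg = MCConfig(n_photons=2000, seed=10)
        a = sweep_grid(grid, spectra, cfg, method=method)
        b = sweep_grid(grid, spectra, cfg, method=method)
        assert a.equals(b)

    def test_empty_grid_rejected(self, spectra):
        with pytest.raises(ValueError):
            sweep_grid([], spectra)

    def test_pathlength_estimator_agrees_with_analog(self, spectra):
        # dual-route check: per-cell simulations vs the shared-path
        # reweighting estimator, compared through their combined MC errors
        grid = [ConcentrationSet(cm_volpct=5, cth_volpct=0.6, sto2_pct=60,
                                 cbil_mgdl=10),
                ConcentrationSet(cm_volpct=1, cth_volpct=0.2, sto2_pct=0)]
        analog = sweep_grid(grid, spectra, MCConfig(n_photons=50_000, seed=21),
                            method="analog")
        pathlen = sweep_grid(grid, spectra,
                             MCConfig(n_photons=200_000, seed=22),
                             method="pathlength")
        rd_cols = [c for c in analog.columns if c.startswith("rd_")]
        se_cols = [c for c in analog.columns if c.startswith("se_")]
        diff = analog[rd_cols].to_numpy() - pathlen[rd_cols].to_numpy()
        se = np.sqrt(analog[se_cols].to_numpy() ** 2
                     + pathlen[se_cols].to_numpy() ** 2)
        assert np.all(np.abs(diff) < 4.5 * se)


class TestValidationOfInputs:
    def test_nonfinite_optical_properties_rejected(self):
        with pytest.raises(ValueError):
            Layer(thickness_cm=0.1, refractive_index=1.4,
                  mua=np.array([np.nan]), mus=np.array([10.0]))

    def test_negative_properties_rejected(self):
        with pytest.raises(ValueError):
            Layer(thickness_cm=0.1, refractive_index=1.4,
                  mua=np.array([-1.0]), mus=np.array([10.0]))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            MCConfig(n_photons=0)
        with pytest.raises(ValueError):
            MCConfig(roulette_survival=0.0)
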