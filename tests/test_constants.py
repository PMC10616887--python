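import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermospec import (ConcentrationSet, UnitConventions,
                       arteriovenous_oxygen_saturation,
                       concentrations_to_molar, dermis_mua, epidermis_mua,
                       molar_to_concentrations)

LN10 = 2.303


class TestChromophoreTable:
    def test_grid_is_the_14_point_visible_band(self, spectra):
        assert spectra.n_bands == 14
        np.testing.assert_array_equal(spectra.wavelengths_nm,
                                      np.arange(460.0, 591.0, 10.0))

    def test_packaged_values_match_source_exactly(self, spectra):
        # the table stores pure-phase absorption coefficients; the loader
        # divides by 2.303 * pure-phase molarity, so multiplying back
        # must recover the tabulated values exactly
        assert spectra.eps_m[0] * LN10 * 0.214 == pytest.approx(
            896.52077, rel=1e-12)
        assert spectra.eps_m[-1] * LN10 * 0.214 == pytest.approx(
            391.38731, rel=1e-12)
        assert spectra.eps_oh[0] * LN10 * 2.32e-3 == pytest.approx(
            240.192, rel=1e-12)
        assert spectra.eps_dh[0] * LN10 * 2.32e-3 == pytest.approx(
            126.29952, rel=1e-12)
        assert spectra.eps_bil[0] == 52924.25352
        assert spectra.musp[0] == 64.94
        assert spectra.musp[-1] == 30.46

    def test_hemoglobin_isosbestic_points(self, spectra):
        # oxy and deoxy whole blood absorb equally near 570 and 585 nm
        wl = spectra.wavelengths_nm
        ratio = spectra.eps_oh / spectra.eps_dh
        assert abs(ratio[wl == 570][0] - 1.0) < 0.02
        # the curves cross between 580 and 590 (isosbestic ~585)
        assert (ratio[wl == 580][0] - 1.0) * (ratio[wl == 590][0] - 1.0) < 0

    def test_deoxygenated_blood_peaks_near_555(self, spectra):
        peak_wl = spectra.wavelengths_nm[np.argmax(spectra.eps_dh)]
        assert peak_wl in (550.0, 560.0)

    def test_bilirubin_peaks_blue_and_vanishes_green(self, spectra):
        assert np.argmax(spectra.eps_bil) == 0
        assert spectra.eps_bil[0] / spectra.eps_bil[8] > 100  # 460 vs 540

    def test_all_values_strictly_positive(self, spectra):
        for arr in (spectra.eps_m, spectra.eps_oh, spectra.eps_dh,
                    spectra.eps_bil, spectra.musp):
            assert np.all(arr > 0)


class TestUnitConversions:
    def test_melanin_one_volpct(self, units):
        m = concentrations_to_molar(ConcentrationSet(cm_volpct=1.0), units)
        assert m.cm_M == pytest.approx(2.14e-3)

    def test_bilirubin_ten_mgdl(self, units):
        # 10 mg/dl = 0.1 g/L; /584.67 g/mol = 1.710e-4 M
        m = concentrations_to_molar(ConcentrationSet(cbil_mgdl=10.0), units)
        assert m.cbil_M == pytest.approx(1.71037e-4, rel=1e-5)

    def test_zero_hemoglobin_gives_zero_molarities(self, units):
        m = concentrations_to_molar(
            ConcentrationSet(cth_volpct=0.0, sto2_pct=50.0), units)
        assert m.coh_M == 0.0 and m.cdh_M == 0.0

    def test_hemoglobin_conventions_differ_tenfold(self):
        dilute = UnitConventions.dilute_blood_convention()
        ratio = (UnitConventions().hemoglobin_molar_per_volpct
                 / dilute.hemoglobin_molar_per_volpct)
        assert ratio == pytest.approx(10.0, rel=0.01)

    def test_oxy_deoxy_sum_to_total_exactly(self):
        c = ConcentrationSet(cth_volpct=0.7, sto2_pct=37.0)
        assert c.coh_volpct + c.cdh_volpct == c.cth_volpct

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(cm=st.floats(0, 20), cth=st.floats(1e-6, 2.0),
           sto2=st.floats(0, 100), cbil=st.floats(0, 30))
    def test_molar_round_trip(self, cm, cth, sto2, cbil):
        u = UnitConventions()
        c = ConcentrationSet(cm, cth, sto2, cbil)
        back = molar_to_concentrations(concentrations_to_molar(c, u), u)
        assert back.cm_volpct == pytest.approx(cm, rel=1e-12, abs=1e-15)
        assert back.cth_volpct == pytest.approx(cth, rel=1e-12)
        assert back.cbil_mgdl == pytest.approx(cbil, rel=1e-12, abs=1e-15)

    @pytest.mark.parametrize("kwargs", [
        {"cm_volpct": -1}, {"cth_volpct": -0.1},
        {"sto2_pct": 101}, {"sto2_pct": -1}, {"cbil_mgdl": -2},
    ])
    def test_invalid_concentrations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ConcentrationSet(**kwargs)


class TestAbsorptionBuilders:
    def test_epidermis_zero_melanin_is_zero(self, spectra, units):
        mua = epidermis_mua(ConcentrationSet(cm_volpct=0), spectra, units)
        assert np.all(mua == 0)

    def test_epidermis_linear_in_melanin(self, spectra, units):
        m1 = epidermis_mua(ConcentrationSet(cm_volpct=1), spectra, units)
        m2 = epidermis_mua(ConcentrationSet(cm_volpct=2), spectra, units)
        np.testing.assert_allclose(m2, 2 * m1, rtol=1e-14)

    def test_epidermis_proportions_melanosome_absorption(self, spectra, units):
        # 1 vol.% melanin = 1% of the melanosome absorption coefficient
        mua = epidermis_mua(ConcentrationSet(cm_volpct=1), spectra, units)
        assert mua[0] == pytest.approx(896.52077 / 100.0, rel=1e-12)
        full = epidermis_mua(ConcentrationSet(cm_volpct=100), spectra, units)
        assert full[0] == pytest.approx(896.52077, rel=1e-12)

    def test_dermis_zero_concentrations(self, spectra, units):
        mua = dermis_mua(ConcentrationSet(), spectra, units)
        assert np.all(mua == 0)

    def test_dermis_proportions_whole_blood_absorption(self, spectra, units):
        # 1 vol.% fully oxygenated blood = 1% of the oxyblood coefficient
        c = ConcentrationSet(cth_volpct=1.0, sto2_pct=100.0)
        mua = dermis_mua(c, spectra, units)
        assert mua[0] == pytest.approx(240.192 / 100.0, rel=1e-12)

    def test_dermis_saturation_extremes_use_one_species(self, spectra, units):
        oxy = dermis_mua(ConcentrationSet(cth_volpct=0.5, sto2_pct=100),
                         spectra, units)
        deoxy = dermis_mua(ConcentrationSet(cth_volpct=0.5, sto2_pct=0),
                           spectra, units)
        coh_M = 0.5 * units.hemoglobin_molar_per_volpct
        np.testing.assert_allclose(oxy, LN10 * coh_M * spectra.eps_oh,
                                   rtol=1e-14)
        np.testing.assert_allclose(deoxy, LN10 * coh_M * spectra.eps_dh,
                                   rtol=1e-14)

    def test_bilirubin_contribution_doubles(self, spectra, units):
        b1 = dermis_mua(ConcentrationSet(cbil_mgdl=5), spectra, units)
        b2 = dermis_mua(ConcentrationSet(cbil_mgdl=10), spectra, units)
        np.testing.assert_allclose(b2, 2 * b1, rtol=1e-14)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(cth1=st.floats(0, 1), cth2=st.floats(0, 1),
           sto2=st.floats(0, 100), cbil1=st.floats(0, 20),
           cbil2=st.floats(0, 20))
    def test_dermis_superposition(self, spectra, units, cth1, cth2, sto2,
                                  cbil1, cbil2):
        a = dermis_mua(ConcentrationSet(0, cth1, sto2, cbil1), spectra, units)
        b = dermis_mua(ConcentrationSet(0, cth2, sto2, cbil2), spectra, units)
        both = dermis_mua(ConcentrationSet(0, cth1 + cth2, sto2,
                                           cbil1 + cbil2), spectra, units)
        np.testing.assert_allclose(a + b, both, rtol=1e-12, atol=1e-18)


class TestArteriovenousMixing:
    def test_resting_skin_value(self):
        assert arteriovenous_oxygen_saturation() == 69.0

    def test_pure_venous_and_pure_arterial(self):
        assert arteriovenous_oxygen_saturation(venous_fraction=1.0) == 60.0
        assert arteriovenous_oxygen_saturation(venous_fraction=0.0) == 96.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            arteriovenous_oxygen_saturation(venous_fraction=1.5)
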