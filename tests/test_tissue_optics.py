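"""Chromophore spectra, absorption (de)composition, scattering power law."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dosicomp.tissue_optics import (
    CHROMOPHORES,
    ChromophoreSet,
    ExtinctionLibrary,
    ScatterParams,
    UnderdeterminedError,
    WavelengthRangeError,
    compose_mua,
    decompose_mua,
    default_extinction_library,
    fit_powerlaw,
    powerlaw_mus,
)

SPOT_WAVELENGTHS = [660.0, 730.0, 800.0, 930.0, 970.0]


class TestExtinctionLibrary:
    def test_invariants(self, lib):
        grid = lib.wavelength_nm
        assert grid[0] == 650 and grid[-1] == 1000
        for name in CHROMOPHORES:
            spec = lib.specific_absorption[name]
            assert spec.shape == grid.shape
            assert np.all(spec >= 0)

    def test_oxy_deoxy_cross_near_isosbestic_point(self, lib):
        o2 = lib.specific_absorption["hbmbo2"]
        r = lib.specific_absorption["hbmbr"]
        diff = o2 - r
        sign_change = np.flatnonzero(np.diff(np.sign(diff)))
        crossings = lib.wavelength_nm[sign_change]
        assert any(770 <= lam <= 830 for lam in crossings)

    def test_water_and_fat_peak_positions(self, lib):
        grid = lib.wavelength_nm
        water_peak = grid[np.argmax(lib.specific_absorption["water"])]
        fat_peak = grid[np.argmax(lib.specific_absorption["fat"])]
        assert 955 <= water_peak <= 985
        assert 920 <= fat_peak <= 940

    def test_csv_round_trip(self, lib, tmp_path):
        path = tmp_path / "extinction.csv"
        lib.to_csv(path)
        back = ExtinctionLibrary.from_csv(path)
        np.testing.assert_allclose(back.wavelength_nm, lib.wavelength_nm)
        for name in CHROMOPHORES:
            np.testing.assert_allclose(
                back.specific_absorption[name], lib.specific_absorption[name]
            )


class TestChromophoreSet:
    def test_derived_fields(self):
        c = ChromophoreSet(hbmbo2=84.0, hbmbr=41.2, water=73.0, fat=1.1)
        assert c.thbmb == pytest.approx(125.2)
        assert c.sto2 == pytest.approx(100 * 84.0 / 125.2)

    def test_sto2_undefined_without_heme(self):
        assert ChromophoreSet(0, 0, 50, 10).sto2 is None

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ChromophoreSet(hbmbo2=-1, hbmbr=0, water=0, fat=0)

    def test_from_summary_splits_by_saturation(self, lean_chrom):
        assert lean_chrom.hbmbo2 == pytest.approx(125.2 * 0.671)
        assert lean_chrom.thbmb == pytest.approx(125.2)


class TestComposeMua:
    def test_zero_concentrations_zero_spectrum(self, lib):
        mua = compose_mua(ChromophoreSet(0, 0, 0, 0), lib)
        assert np.all(mua == 0)

    def test_linearity_under_doubling(self, lib, lean_chrom):
        doubled = ChromophoreSet(
            2 * lean_chrom.hbmbo2, 2 * lean_chrom.hbmbr,
            2 * lean_chrom.water, 2 * lean_chrom.fat,
        )
        np.testing.assert_allclose(
            compose_mua(doubled, lib), 2 * compose_mua(lean_chrom, lib), rtol=1e-12
        )

    def test_matches_hand_summed_oracle_at_spot_wavelengths(self, lib, lean_chrom):
        """Independent weighted-sum evaluation of eps*c at 5 wavelengths."""
        mua = compose_mua(lean_chrom, lib, SPOT_WAVELENGTHS)
        for i, lam in enumerate(SPOT_WAVELENGTHS):
            j = int(np.flatnonzero(lib.wavelength_nm == lam)[0])
            expected = (
                lib.specific_absorption["hbmbo2"][j] * lean_chrom.hbmbo2
                + lib.specific_absorption["hbmbr"][j] * lean_chrom.hbmbr
                + lib.specific_absorption["water"][j] / 100.0 * lean_chrom.water
                + lib.specific_absorption["fat"][j] / 100.0 * lean_chrom.fat
            )
            assert mua[i] == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_wavelength_rejected(self, lib, lean_chrom):
        with pytest.raises(WavelengthRangeError):
            compose_mua(lean_chrom, lib, [640.0])
        with pytest.raises(WavelengthRangeError):
            compose_mua(lean_chrom, lib, [1010.0])


class TestDecomposeMua:
    def test_zero_spectrum_zero_concentrations(self, lib):
        c = decompose_mua(np.zeros(lib.wavelength_nm.size), lib)
        assert c.thbmb == 0 and c.water == 0 and c.fat == 0

    def test_underdetermined_rejected(self, lib):
        with pytest.raises(UnderdeterminedError):
            decompose_mua([0.01, 0.01, 0.01], lib, grid=[700.0, 800.0, 900.0])

    def test_outputs_non_negative_even_for_unmixable_spectrum(self, lib, rng):
        # spectrum that no non-negative mixture produced exactly
        mua = compose_mua(
            ChromophoreSet(50, 20, 40, 10), lib
        ) - 0.8 * compose_mua(ChromophoreSet(0, 0, 30, 0), lib)
        c = decompose_mua(np.clip(mua, 1e-9, None), lib)
        assert min(c.hbmbo2, c.hbmbr, c.water, c.fat) >= 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hbmbo2=st.floats(0, 150), hbmbr=st.floats(0, 150),
        water=st.floats(0, 100), fat=st.floats(0, 100),
    )
    def test_round_trip_property(self, hbmbo2, hbmbr, water, fat):
        """compose then decompose recovers any non-negative composition."""
        lib = default_extinction_library()
        truth = ChromophoreSet(hbmbo2, hbmbr, water, fat)
        rec = decompose_mua(compose_mua(truth, lib), lib)
        scale = max(truth.thbmb + truth.water + truth.fat, 1.0)
        np.testing.assert_allclose(
            rec.as_vector(), truth.as_vector(), atol=1e-6 * scale
        )

    @pytest.mark.parametrize("endmember", ["lean_chrom", "fat_chrom"])
    def test_noisy_recovery_of_water_and_fat(self, request, lib, rng, endmember):
        """Additive noise at 1% of spectrum max perturbs water/fat by < 3 pp
        in the median."""
        truth = request.getfixturevalue(endmember)
        mua = compose_mua(truth, lib)
        sigma = 0.01 * mua.max()
        errs_water, errs_fat = [], []
        for _ in range(60):
            noisy = np.clip(mua + rng.normal(0, sigma, mua.shape), 1e-9, None)
            rec = decompose_mua(noisy, lib)
            errs_water.append(abs(rec.water - truth.water))
            errs_fat.append(abs(rec.fat - truth.fat))
        assert np.median(errs_water) < 3.0
        assert np.median(errs_fat) < 3.0


class TestPowerlaw:
    def test_flat_spectrum_when_power_zero(self):
        mus = powerlaw_mus(ScatterParams(1.0, 0.0), [650, 800, 1000])
        np.testing.assert_allclose(mus, 1.0)

    def test_hand_evaluated_value_at_800(self):
        # a500 * (800/500)^(-b) with muscle-like magnitudes
        mus = powerlaw_mus(ScatterParams(0.87, 1.28), [800.0])
        assert mus[0] == pytest.approx(0.87 * 1.6 ** (-1.28), rel=1e-12)
        assert mus[0] == pytest.approx(0.476, abs=5e-3)

    @pytest.mark.parametrize("b", [-0.5, 0.0, 0.7, 2.2])
    def test_reference_wavelength_identity(self, b):
        assert powerlaw_mus(ScatterParams(1.3, b), [500.0])[0] == pytest.approx(1.3)

    def test_mus800_derived_field(self):
        p = ScatterParams(0.85, 0.42)
        assert p.mus800 == pytest.approx(0.85 * 1.6 ** (-0.42), rel=1e-12)

    def test_invalid_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ScatterParams(0.0, 1.0)

    def test_negative_sign_convention_loader(self):
        p = ScatterParams.from_reported(0.87, -1.28, negative_convention=True)
        assert p.b_power == pytest.approx(1.28)
        # scattering must decrease with wavelength for normal tissue
        mus = powerlaw_mus(p, [650.0, 1000.0])
        assert mus[0] > mus[1]


class TestFitPowerlaw:
    def test_exact_recovery_from_noiseless_points(self):
        truth = ScatterParams(0.85, 0.42)
        lams = [690.0, 785.0, 835.0]
        fit = fit_powerlaw(lams, powerlaw_mus(truth, lams))
        assert fit.a500 == pytest.approx(0.85, rel=1e-10)
        assert fit.b_power == pytest.approx(0.42, rel=1e-10)

    def test_constant_input_gives_zero_power(self):
        fit = fit_powerlaw([690.0, 785.0, 835.0], [0.7, 0.7, 0.7])
        assert fit.b_power == pytest.approx(0.0, abs=1e-12)
        assert fit.a500 == pytest.approx(0.7)

    def test_self_consistent_at_reference_wavelength(self):
        fit = fit_powerlaw([600.0, 900.0], [1.1, 0.6])
        assert powerlaw_mus(fit, [500.0])[0] == pytest.approx(fit.a500)

    def test_two_points_interpolates(self):
        lams, mus = [700.0, 900.0], [0.9, 0.55]
        fit = fit_powerlaw(lams, mus)
        np.testing.assert_allclose(powerlaw_mus(fit, lams), mus, rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k=st.floats(0.1, 10), b=st.floats(-1, 3))
    def test_scale_equivariance(self, k, b):
        """Scaling mus' by k scales a500 by k and leaves the power unchanged."""
        lams = np.array([690.0, 785.0, 835.0])
        base = 0.9 * (lams / 500.0) ** (-b)
        fit = fit_powerlaw(lams, k * base)
        assert fit.a500 == pytest.approx(k * 0.9, rel=1e-8)
        assert fit.b_power == pytest.approx(b, abs=1e-8)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_powerlaw([690.0, 785.0], [1.0, -0.1])
        with pytest.raises(ValueError):
            fit_powerlaw([690.0], [1.0])
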