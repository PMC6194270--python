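"""Processing operations: averaging, subtraction, zeroing, smoothing,
unit conversion, scaling, calibration, HT truncation, error bands."""

import numpy as np
import pytest

from cdspectra import (
    SampleInfo,
    Spectrum,
    WavelengthWindow,
    apply_calibration,
    average_spectra,
    compute_calibration_factor,
    error_band,
    scale_to_value,
    smooth_sg,
    subtract_baseline,
    subtract_baseline_multi,
    to_delta_epsilon,
    to_mre,
    truncate_by_ht,
    zero_spectrum,
)
from cdspectra import synth
from tests.conftest import random_spectrum


def flat(values, **kw):
    values = np.asarray(values, dtype=float)
    wl = 260.0 - np.arange(values.size)
    return Spectrum(wavelengths=wl, cd=values, **kw)


class TestAverage:
    def test_identical_replicates_average_to_themselves_with_zero_sd(self, helix):
        avg = average_spectra([helix, helix.copy()])
        np.testing.assert_allclose(avg.cd, helix.cd)
        assert np.all(avg.sd == 0)
        assert avg.n_averaged == 2

    def test_hand_computed_mean_and_sample_sd(self):
        spectra = [flat([v, v]) for v in (1.0, 2.0, 3.0)]
        avg = average_spectra(spectra)
        np.testing.assert_allclose(avg.cd, 2.0)
        np.testing.assert_allclose(avg.sd, 1.0)  # sample SD of {1,2,3}

    def test_matches_brute_force_loop_oracle(self, rng):
        """Mean/SD agree with an explicit loop on 100 random replicate sets."""
        for _ in range(100):
            n_rep = int(rng.integers(2, 7))
            base = random_spectrum(rng)
            reps = synth.make_replicates(base, n_rep, 0.5, seed=int(rng.integers(2**31)))
            avg = average_spectra(reps)
            for j in range(base.n_points):
                values = [r.cd[j] for r in reps]
                mean = sum(values) / n_rep
                var = sum((v - mean) ** 2 for v in values) / (n_rep - 1)
                assert avg.cd[j] == pytest.approx(mean, abs=1e-12)
                assert avg.sd[j] == pytest.approx(var**0.5, abs=1e-12)

    def test_fewer_than_two_spectra_rejected(self, helix):
        with pytest.raises(ValueError):
            average_spectra([helix])

    def test_mixed_units_rejected(self, helix):
        other = helix.copy()
        other.units = "MRE"
        with pytest.raises(ValueError, match="units"):
            average_spectra([helix, other])


class TestSubtract:
    def test_self_subtraction_gives_zero(self, helix):
        out = subtract_baseline(helix, helix)
        np.testing.assert_array_equal(out.cd, 0.0)

    def test_pointwise_difference(self):
        out = subtract_baseline(flat([10.0, 10.0]), flat([3.0, 3.0]))
        np.testing.assert_allclose(out.cd, 7.0)

    def test_sd_propagates_in_quadrature(self):
        s = flat([1.0, 1.0], sd=[3.0, 3.0], n_averaged=2)
        b = flat([0.0, 0.0], sd=[4.0, 4.0], n_averaged=2)
        out = subtract_baseline(s, b)
        np.testing.assert_allclose(out.sd, 5.0)

    def test_subtract_then_add_recovers_original(self, rng):
        for _ in range(20):
            s = random_spectrum(rng)
            b = s.replace(cd=rng.normal(0, 2, s.n_points))
            back = subtract_baseline(subtract_baseline(s, b), b.replace(cd=-b.cd))
            np.testing.assert_allclose(back.cd, s.cd, atol=1e-12)

    def test_multi_applies_one_baseline_to_each_sample(self, helix):
        outs = subtract_baseline_multi([helix, helix.copy()], helix)
        assert len(outs) == 2
        for out in outs:
            np.testing.assert_array_equal(out.cd, 0.0)

    def test_multi_rejects_empty_sample_list(self, helix):
        with pytest.raises(ValueError):
            subtract_baseline_multi([], helix)


class TestZero:
    def test_constant_spectrum_zeroes_everywhere(self):
        out = zero_spectrum(flat([5.0] * 10), WavelengthWindow(250.0, 260.0))
        np.testing.assert_allclose(out.cd, 0.0, atol=1e-12)

    def test_offset_is_window_mean(self):
        # cd = {4, 6} inside the window -> offset -5 applied everywhere
        s = flat([4.0, 6.0, 10.0])
        out = zero_spectrum(s, WavelengthWindow(258.5, 260.5))
        np.testing.assert_allclose(out.cd, [-1.0, 1.0, 5.0])

    def test_window_mean_is_zero_after(self, rng):
        s = random_spectrum(rng)
        w = WavelengthWindow(float(s.wavelengths[-1]), float(s.wavelengths[0]))
        out = zero_spectrum(s, w)
        assert abs(out.cd[w.mask(out.wavelengths)].mean()) < 1e-12

    def test_window_outside_grid_rejected(self, helix):
        with pytest.raises(ValueError, match="outside"):
            zero_spectrum(helix, WavelengthWindow(300.0, 310.0))


class TestSmoothSG:
    @pytest.mark.parametrize("order,window", [(1, 5), (2, 7), (2, 11), (3, 9)])
    def test_reproduces_polynomials_up_to_filter_order(self, order, window):
        wl = 260.0 - np.arange(41)
        coeffs = np.arange(order + 1) + 0.5
        cd = np.polyval(coeffs, (wl - 220.0) / 10.0)
        out = smooth_sg(Spectrum(wavelengths=wl, cd=cd), window, order)
        np.testing.assert_allclose(out.cd_smoothed, cd, atol=1e-10)
        np.testing.assert_array_equal(out.cd, cd)  # raw channel untouched

    def test_constant_signal_is_unchanged(self):
        out = smooth_sg(flat([3.0] * 15), 7, 2)
        np.testing.assert_allclose(out.cd_smoothed, 3.0, atol=1e-12)

    @pytest.mark.parametrize("window,order,msg", [
        (6, 2, "odd"), (3, 2, "poly_order"), (101, 2, "exceeds"),
    ])
    def test_invalid_parameters_rejected(self, helix, window, order, msg):
        with pytest.raises(ValueError, match=msg):
            smooth_sg(helix, window, order)

    def test_uneven_grid_rejected(self):
        s = Spectrum(wavelengths=[260.0, 259.0, 257.0, 256.0, 255.0, 254.0, 253.0],
                     cd=np.zeros(7))
        with pytest.raises(ValueError, match="evenly spaced"):
            smooth_sg(s, 5, 2)


class TestUnitConversion:
    INFO = SampleInfo(concentration=1.0, molecular_weight=11000.0,
                      n_residues=101, pathlength=0.1)

    def test_mre_hand_example(self):
        # theta 10 mdeg, MRW 110, c 1 mg/mL, l 0.1 cm:
        # 10 * 110 / (10 * 1 * 0.1) = 1100 deg cm2/dmol
        out = to_mre(flat([10.0, 10.0]), self.INFO)
        np.testing.assert_allclose(out.cd, 1100.0)
        assert out.units == "MRE"

    def test_zero_maps_to_zero(self):
        out = to_mre(flat([0.0, 0.0]), self.INFO)
        np.testing.assert_array_equal(out.cd, 0.0)

    def test_doubling_concentration_halves_mre(self):
        double = SampleInfo(concentration=2.0, molecular_weight=11000.0,
                            n_residues=101, pathlength=0.1)
        a = to_mre(flat([10.0, 4.0]), self.INFO)
        b = to_mre(flat([10.0, 4.0]), double)
        np.testing.assert_allclose(b.cd, a.cd / 2.0)

    def test_delta_epsilon_definitional_constant(self):
        s = flat([3298.0, 0.0], units="MRE")
        out = to_delta_epsilon(s)
        np.testing.assert_allclose(out.cd, [1.0, 0.0])
        assert out.units == "delta_epsilon"

    def test_mdeg_to_de_path_independence(self, rng):
        s = random_spectrum(rng)
        direct = to_delta_epsilon(s, self.INFO)
        via_mre = to_delta_epsilon(to_mre(s, self.INFO))
        np.testing.assert_allclose(direct.cd, via_mre.cd, atol=1e-12)

    def test_conversions_are_linear(self, rng):
        s = random_spectrum(rng)
        scaled = s.replace(cd=3.5 * s.cd, sd=3.5 * s.sd,
                           cd_smoothed=3.5 * s.cd_smoothed)
        np.testing.assert_allclose(
            to_mre(scaled, self.INFO).cd, 3.5 * to_mre(s, self.INFO).cd, rtol=1e-12
        )

    def test_wrong_input_units_rejected(self):
        with pytest.raises(ValueError, match="mdeg"):
            to_mre(flat([1.0, 2.0], units="MRE"), self.INFO)
        with pytest.raises(ValueError):
            to_delta_epsilon(flat([1.0, 2.0], units="delta_epsilon"))


class TestScaleAndCalibrate:
    def test_scaling_to_current_value_is_identity(self):
        s = flat([5.0, 2.0])
        out = scale_to_value(s, at=260.0, target=5.0)
        np.testing.assert_allclose(out.cd, s.cd)

    def test_scaling_doubles_every_point(self):
        out = scale_to_value(flat([5.0, 2.0]), at=260.0, target=10.0)
        np.testing.assert_allclose(out.cd, [10.0, 4.0])

    def test_zero_anchor_value_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            scale_to_value(flat([0.0, 2.0]), at=260.0, target=1.0)

    def test_calibration_factor_is_expected_over_measured(self):
        assert compute_calibration_factor(30.0, 33.0) == pytest.approx(1.1)

    def test_unit_factor_is_identity(self, helix):
        out = apply_calibration(helix, 1.0)
        np.testing.assert_array_equal(out.cd, helix.cd)

    def test_factor_two_doubles_signal(self, helix):
        out = apply_calibration(helix, 2.0, note="CSA standard ratio")
        np.testing.assert_allclose(out.cd, 2.0 * helix.cd)
        assert "CSA" in out.meta["processing"]

    def test_non_positive_factor_rejected(self, helix):
        with pytest.raises(ValueError):
            apply_calibration(helix, -0.5)


class TestTruncateByHT:
    def test_clean_ht_leaves_spectrum_unchanged(self, helix_with_ht):
        out, cutoff = truncate_by_ht(helix_with_ht, ht_max=1e6)
        assert cutoff is None
        np.testing.assert_array_equal(out.wavelengths, helix_with_ht.wavelengths)

    def test_constructed_crossing_is_recovered_exactly(self):
        # base 300 V, knee 200 nm, slope 40 V/nm on a 260->175 nm grid:
        # HT first exceeds 600 V below 200 - 300/40 = 192.5 nm, i.e. at
        # 192 nm on the integer grid, so the cutoff is 193 nm.
        s = synth.make_band_spectrum(synth.HELIX_BANDS, grid=(260.0, 175.0, 1.0))
        s = synth.make_ht_profile(s, base=300.0, knee=200.0, slope=40.0)
        out, cutoff = truncate_by_ht(s, ht_max=600.0)
        assert cutoff == 193.0
        assert out.wavelengths[-1] == 193.0
        assert np.all(out.ht <= 600.0)

    def test_retained_range_is_contiguous_suffix_from_top(self, rng):
        for _ in range(20):
            s = random_spectrum(rng)
            try:
                out, cutoff = truncate_by_ht(s, ht_max=float(np.median(s.ht)))
            except ValueError:
                continue  # highest-wavelength point already bad
            assert out.wavelengths[0] == s.wavelengths[0]
            n = out.n_points
            np.testing.assert_array_equal(out.wavelengths, s.wavelengths[:n])

    def test_all_points_bad_is_an_error(self, helix_with_ht):
        with pytest.raises(ValueError, match="no data retained"):
            truncate_by_ht(helix_with_ht, ht_max=0.0)

    def test_missing_ht_channel_is_an_error(self, helix):
        with pytest.raises(ValueError, match="HT"):
            truncate_by_ht(helix, ht_max=600.0)


class TestErrorBand:
    def test_hand_computed_band(self):
        s = flat([3.0, 3.0], sd=[0.5, 0.5], n_averaged=2)
        bands = error_band(s, k_sigma=2.0, interval=1.0)
        assert bands[0] == (260.0, 2.0, 4.0)

    def test_zero_sd_collapses_band(self):
        s = flat([3.0, 4.0], sd=[1e-9, 1e-9], n_averaged=2)
        for lam, lo, hi in error_band(s, k_sigma=1.0, interval=1.0):
            assert hi - lo == pytest.approx(2e-9)

    def test_interval_wider_than_span_returns_single_point(self):
        s = flat([1.0, 2.0, 3.0], sd=[0.1] * 3, n_averaged=2)
        assert len(error_band(s, interval=100.0)) == 1

    def test_requires_an_averaged_spectrum(self, helix):
        with pytest.raises(ValueError, match="replicate"):
            error_band(helix)
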