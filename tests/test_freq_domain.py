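"""Frequency-domain stages: FT, referencing, phasing, region removal,
baselines, zeroing, windowing."""

import numpy as np
import pytest

from nmrprep import (FidSet, PeakSpec, SpectrumSet, StageError,
                     baseline_correction, fourier_transform,
                     internal_referencing, negative_values_zeroing,
                     phase_correction, region_removal, simulate_fid,
                     window_selection, zero_filling)
from nmrprep.freq_domain import phase_objective


def _spectrum(rows, axis=None, ids=None):
    rows = np.atleast_2d(rows)
    if axis is None:
        axis = np.linspace(12.0, -2.0, rows.shape[1])
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return SpectrumSet(rows, axis, ids)


class TestFourierTransform:
    def test_constant_fid_peaks_at_carrier(self, make_params):
        params = make_params(sw_h=1000.0, sfo1=500.0, o1=2350.0)
        fids = FidSet(np.ones((1, 256), dtype=complex), 1 / 1000.0, ["s0"])
        sp = fourier_transform(fids, params)
        peak_ppm = sp.ppm_axis[np.argmax(np.abs(sp.intensities[0]))]
        assert abs(peak_ppm - 2350.0 / 500.0) <= sp.ppm_step()

    def test_offset_peak_maps_to_ppm(self, make_params):
        # +500 Hz offset at SFO1 = 500 MHz, O1 = 2350 Hz -> 5.700 ppm
        sw_h, sfo1, o1 = 6000.0, 500.0, 2350.0
        fid = simulate_fid([PeakSpec(5.7, 1.0, 0.5)], 8192, sw_h, sfo1, o1=o1)
        sp = fourier_transform(
            FidSet(fid[None, :], 1 / sw_h, ["s0"]),
            make_params(sw_h=sw_h, sfo1=sfo1, o1=o1))
        peak_ppm = sp.ppm_axis[np.argmax(np.abs(sp.intensities[0]))]
        assert abs(peak_ppm - 5.700) <= sp.ppm_step()

    def test_parseval_identity(self, make_params):
        rng = np.random.default_rng(1)
        row = rng.normal(size=512) + 1j * rng.normal(size=512)
        sp = fourier_transform(FidSet(row[None, :], 1e-4, ["s0"]),
                               make_params())
        lhs = np.sum(np.abs(row) ** 2)
        rhs = np.sum(np.abs(sp.intensities[0]) ** 2) / 512
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_axis_is_strictly_decreasing(self, make_params):
        sp = fourier_transform(
            FidSet(np.ones((1, 64), dtype=complex), 1e-4, ["s0"]),
            make_params())
        assert np.all(np.diff(sp.ppm_axis) < 0)

    def test_missing_sw_raises(self, make_params):
        params = make_params().drop(columns=["SW_h"])
        with pytest.raises(StageError, match="SW_h"):
            fourier_transform(
                FidSet(np.ones((1, 8), dtype=complex), 1e-4, ["s0"]), params)


class TestInternalReferencing:
    def _axis(self, m=2001):
        return np.linspace(1.0, -1.0, m)

    def _peak_row(self, axis, ppm, width=0.01):
        return np.exp(-((axis - ppm) / width) ** 2).astype(complex)

    def test_offset_peak_moved_to_zero(self):
        axis = self._axis()
        sp = SpectrumSet(self._peak_row(axis, 0.05)[None, :], axis, ["a"])
        ref = internal_referencing(sp)
        i0 = np.argmin(np.abs(axis))
        assert np.argmax(np.abs(ref.intensities[0])) == i0

    def test_peak_already_at_zero_is_identity(self):
        axis = self._axis()
        sp = SpectrumSet(self._peak_row(axis, 0.0)[None, :], axis, ["a"])
        ref = internal_referencing(sp)
        np.testing.assert_array_equal(ref.intensities, sp.intensities)

    def test_two_samples_land_on_same_point(self):
        axis = self._axis()
        rows = np.vstack([self._peak_row(axis, 0.05),
                          self._peak_row(axis, -0.08)])
        ref, offsets = internal_referencing(
            SpectrumSet(rows, axis, ["a", "b"]), return_offsets=True)
        maxima = np.argmax(np.abs(ref.intensities), axis=1)
        assert maxima[0] == maxima[1]
        assert offsets[0] != offsets[1]

    def test_window_off_axis_raises(self):
        axis = np.linspace(10.0, 5.0, 100)
        sp = SpectrumSet(np.ones((1, 100), dtype=complex), axis, ["a"])
        with pytest.raises(StageError, match="window"):
            internal_referencing(sp)


class TestPhaseCorrection:
    def _simulated_spectrum(self, phi_error, seed=0, noise=0.02):
        sw_h, sfo1, o1 = 7201.56, 600.13, 2820.611
        peaks = [PeakSpec(1.3, 5.0, 0.5), PeakSpec(3.0, 8.0, 0.4),
                 PeakSpec(7.8, 2.0, 0.3), PeakSpec(0.0, 4.0, 1.0)]
        fid = simulate_fid(peaks, 8192, sw_h, sfo1, phase_error=phi_error,
                           noise_sd=noise, seed=seed, o1=o1)
        # apodize as the pipeline does pre-FT: truncation ringing
        # otherwise biases the positive-RMS objective by ~1 degree
        from nmrprep import apodization
        fids = zero_filling(apodization(
            FidSet(fid[None, :], 1 / sw_h, ["s0"]), "exponential", 1.0))
        import pandas as pd
        params = pd.DataFrame({"SW_h": [sw_h], "SFO1": [sfo1], "O1": [o1]},
                              index=["s0"])
        return fourier_transform(fids, params)

    def test_recovers_injected_30_degrees(self):
        sp = self._simulated_spectrum(np.deg2rad(30.0))
        _, result = phase_correction(sp)
        assert np.rad2deg(result.angles[0]) == pytest.approx(-30.0, abs=1.0)

    def test_zero_error_recovers_zero(self):
        sp = self._simulated_spectrum(0.0)
        _, result = phase_correction(sp)
        assert abs(np.rad2deg(result.angles[0])) < 1.0

    def test_optimum_beats_half_degree_grid(self):
        sp = self._simulated_spectrum(np.deg2rad(117.0), seed=5)
        _, result = phase_correction(sp)
        grid = np.deg2rad(np.arange(-180.0, 180.0, 0.5))
        best_grid = max(phase_objective(sp.intensities[0], g) for g in grid)
        assert result.objectives[0] >= best_grid - 1e-9 * abs(best_grid)

    def test_gauge_invariance(self):
        sp = self._simulated_spectrum(np.deg2rad(40.0), seed=2)
        corrected, _ = phase_correction(sp)
        rotated = sp.with_intensities(sp.intensities * np.exp(1j * 0.7))
        corrected2, _ = phase_correction(rotated)
        scale = np.max(np.abs(corrected.intensities))
        np.testing.assert_allclose(corrected2.intensities,
                                   corrected.intensities,
                                   atol=1e-6 * scale)

    def test_all_zero_spectrum_warns_angle_zero(self):
        sp = _spectrum(np.zeros(64, dtype=complex))
        with pytest.warns(UserWarning, match="all-zero"):
            _, result = phase_correction(sp)
        assert result.angles[0] == 0.0


class TestRegionRemoval:
    def test_urine_preset_zeroes_span(self):
        axis = np.linspace(12.0, -2.0, 1401)
        sp = SpectrumSet(np.ones((2, 1401)), axis, ["a", "b"])
        out = region_removal(sp, "urine")
        mask = (axis >= 4.5) & (axis <= 6.1)
        assert not np.any(out.intensities[:, mask])
        assert np.all(out.intensities[:, ~mask] == 1.0)

    def test_empty_region_list_is_identity(self):
        sp = _spectrum(np.random.default_rng(0).normal(size=128))
        out = region_removal(sp, [])
        np.testing.assert_array_equal(out.intensities, sp.intensities)

    def test_area_bookkeeping(self):
        axis = np.linspace(10.0, 0.0, 1001)
        y = np.full(1001, 2.0)
        sp = SpectrumSet(y[None, :], axis, ["a"])
        out = region_removal(sp, [(4.0, 6.0)])
        area_before = np.trapezoid(y[::-1], axis[::-1])
        area_after = np.trapezoid(out.intensities[0][::-1], axis[::-1])
        # zeroed span of 2 ppm at height 2, plus the two boundary
        # trapezoid half-steps
        removed = area_before - area_after
        assert removed == pytest.approx(2.0 * 2.0 + 2.0 * 0.01, rel=1e-9)

    def test_inverted_bounds_raise(self):
        sp = _spectrum(np.ones(64))
        with pytest.raises(StageError, match="inverted"):
            region_removal(sp, [(6.1, 4.5)])

    def test_off_axis_region_warns(self):
        sp = SpectrumSet(np.ones((1, 64)), np.linspace(2.0, 0.0, 64), ["a"])
        with pytest.warns(UserWarning, match="clipped"):
            region_removal(sp, [(5.0, 6.0)])


class TestBaselineCorrection:
    @staticmethod
    def _peaky(m=2048, seed=0):
        x = np.arange(m)
        signal = np.zeros(m)
        centers = [300, 700, 1200, 1700]
        for c in centers:
            signal += 100.0 * 16.0 / ((x - c) ** 2 + 16.0)
        offpeak = np.ones(m, bool)
        for c in centers:
            offpeak[c - 50:c + 50] = False
        noise = np.random.default_rng(seed).normal(0, 0.05, m)
        return signal, offpeak, noise

    @pytest.mark.parametrize("method", ["als", "arpls", "airpls"])
    def test_constant_offset_recovered(self, method):
        signal, offpeak, noise = self._peaky()
        c = 10.0
        sp = _spectrum(signal + c + noise)
        out = baseline_correction(sp, method)
        assert np.median(np.abs(out.intensities[0][offpeak])) < 0.02 * c

    @pytest.mark.parametrize("method", ["als", "arpls", "airpls"])
    def test_zero_spectrum_stays_zero(self, method):
        out = baseline_correction(_spectrum(np.zeros(512)), method)
        assert not np.any(out.intensities)

    @pytest.mark.parametrize("method", ["als", "arpls", "airpls"])
    def test_pure_linear_ramp_removed(self, method):
        ramp = np.linspace(0.0, 50.0, 1024)
        out = baseline_correction(_spectrum(ramp), method)
        assert np.max(np.abs(out.intensities[0])) < 0.01 * 50.0

    def test_unknown_method_raises(self):
        with pytest.raises(StageError, match="unknown baseline"):
            baseline_correction(_spectrum(np.ones(64)), "rubberband")

    def test_baseline_subtracted_not_added(self):
        signal, _, noise = self._peaky(seed=3)
        y = signal + 5.0 + noise
        sp = _spectrum(y)
        out = baseline_correction(sp, "arpls")
        z = y - out.intensities[0]  # the implied baseline estimate
        where_pos = z >= 0
        assert np.all(out.intensities[0][where_pos] <= y[where_pos] + 1e-12)


class TestNegativeValuesZeroing:
    def test_examples_and_idempotence(self):
        sp = _spectrum(np.array([-1.0, 2.0, -3.0]))
        out = negative_values_zeroing(sp)
        np.testing.assert_array_equal(out.intensities[0], [0.0, 2.0, 0.0])
        again = negative_values_zeroing(out)
        np.testing.assert_array_equal(again.intensities, out.intensities)

    def test_nonnegative_input_unchanged(self):
        sp = _spectrum(np.abs(np.random.default_rng(0).normal(size=64)))
        out = negative_values_zeroing(sp)
        np.testing.assert_array_equal(out.intensities, sp.intensities)


class TestWindowSelection:
    def test_defaults_trim_to_span(self):
        axis = np.linspace(14.0, -2.0, 1601)
        sp = SpectrumSet(np.ones((1, 1601)), axis, ["a"])
        out = window_selection(sp)
        assert out.ppm_axis[0] <= 10.0 and out.ppm_axis[-1] >= 0.2
        assert out.ppm_axis.size == np.count_nonzero(
            (axis >= 0.2) & (axis <= 10.0))

    def test_full_cover_window_is_identity(self):
        sp = _spectrum(np.arange(100.0))
        out = window_selection(sp, ppm_lo=-100.0, ppm_hi=100.0)
        np.testing.assert_array_equal(out.intensities, sp.intensities)

    def test_idempotent(self):
        sp = _spectrum(np.random.default_rng(2).normal(size=512))
        once = window_selection(sp, 0.2, 10.0)
        twice = window_selection(once, 0.2, 10.0)
        np.testing.assert_array_equal(twice.intensities, once.intensities)

    def test_empty_intersection_raises(self):
        sp = SpectrumSet(np.ones((1, 50)), np.linspace(2.0, 1.0, 50), ["a"])
        with pytest.raises(StageError):
            window_selection(sp, 8.0, 9.0)
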