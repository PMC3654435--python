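"""ROI traces, amplitudes, normalization, maps and the display transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glvchoice import imaging, response, synthgen
from glvchoice.movie import AcquisitionGeometry, DffMovie
from glvchoice.response import (ActivationMap, ResponseTrace, Roi,
                                ResponseAmplitude)


def _dff(arr, geometry):
    arr = np.asarray(arr, dtype=float)
    return DffMovie(dff=arr, f0=np.ones(arr.shape[1:]),
                    baseline_frames=np.arange(8), geometry=geometry)


class TestExtractTrace:
    def test_zero_dff_gives_zero_trace(self, small_geometry):
        dff = _dff(np.zeros((40, 64, 80)), small_geometry)
        trace = response.extract_trace(dff, Roi("r", 32, 40))
        assert np.all(trace.values == 0)

    def test_uniform_frame_value_appears_in_trace(self, small_geometry):
        arr = np.zeros((40, 64, 80))
        arr[17] = 0.2
        trace = response.extract_trace(_dff(arr, small_geometry), Roi("r", 32, 40))
        assert trace.values[17] == pytest.approx(0.2)

    def test_roi_side_is_24_px_at_default_pixel_size(self):
        assert Roi("r", 100, 100).side_px(2.5) == 24

    def test_roi_outside_frame_rejected(self, small_geometry):
        dff = _dff(np.zeros((40, 64, 80)), small_geometry)
        with pytest.raises(ValueError, match="outside"):
            response.extract_trace(dff, Roi("r", 2, 2))

    def test_synthetic_spot_trace_peak_near_truth(self, small_geometry,
                                                  small_truth):
        movie, _ = synthgen.generate_al_movie(small_truth, small_geometry,
                                              odor="stim")
        result = imaging.preprocess(movie, motion=False,
                                    bleach_exclude=(8, 32))
        g = small_truth.glomeruli[0]
        trace = response.extract_trace(result.dff,
                                       Roi("r", g.center_row_px, g.center_col_px))
        clean = synthgen.noiseless_roi_dff(
            small_truth, small_geometry, (g.center_row_px, g.center_col_px),
            24, odor="stim")
        assert trace.values.max() == pytest.approx(clean.max(), rel=0.10)


class TestSmoothTrace:
    def test_three_frame_mean_with_boundary_shrink(self):
        trace = ResponseTrace(np.array([0.0, 3, 0, 3, 0]), "r")
        out = response.smooth_trace(trace)
        assert np.allclose(out.values, [1.5, 1.0, 2.0, 1.0, 1.5])
        assert out.smoothed

    def test_constant_trace_unchanged(self):
        trace = ResponseTrace(np.full(10, 0.7), "r")
        assert np.allclose(response.smooth_trace(trace).values, 0.7)

    def test_matches_bruteforce_windowed_mean(self, rng):
        v = rng.normal(size=40)
        out = response.smooth_trace(ResponseTrace(v, "r"), window=3).values
        expected = np.array([v[max(i - 1, 0):i + 2].mean() for i in range(40)])
        assert np.allclose(out, expected)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            response.smooth_trace(ResponseTrace(np.zeros(5), "r"), window=2)


class TestResponseAmplitude:
    def test_peak_averaged_with_neighbours(self):
        trace = ResponseTrace(np.array([0.0, 0.2, 0.5, 0.4, 0.1]), "r",
                              smoothed=True)
        assert response.response_amplitude(trace, 1) == \
            pytest.approx((0.2 + 0.5 + 0.4) / 3)

    def test_peak_at_final_frame_uses_last_two(self):
        trace = ResponseTrace(np.array([0.0, 0.1, 0.2, 0.3, 0.9]), "r",
                              smoothed=True)
        assert response.response_amplitude(trace, 1) == pytest.approx(0.6)

    @pytest.mark.parametrize("peak_at", range(1, 10))
    def test_matches_bruteforce_over_argmax_positions(self, peak_at, rng):
        v = -np.abs(rng.normal(size=10))
        v[peak_at] = 1.0
        onset = 1
        est = response.response_amplitude(ResponseTrace(v, "r"), onset)
        k = onset + int(np.argmax(v[onset:]))
        expected = np.mean(v[max(k - 1, 0):k + 2])
        assert est == pytest.approx(expected)

    def test_onset_beyond_trace_rejected(self):
        with pytest.raises(ValueError):
            response.response_amplitude(ResponseTrace(np.zeros(5), "r"), 4)


class TestNormalization:
    @staticmethod
    def _amps(raws, odors=None):
        odors = odors or [f"odor{i}" for i in range(len(raws))]
        return [ResponseAmplitude("a0", f"ROI{i + 1}", odors[i], 250.0, r)
                for i, r in enumerate(raws)]

    def test_percent_of_animal_maximum(self):
        out = response.normalize_amplitudes(self._amps([0.5, 1.0, 0.2]))
        assert [a.normalized_pct for a in out] == [50.0, 100.0, 20.0]
        assert [a.included for a in out] == [True, True, False]

    def test_single_response_is_its_own_maximum(self):
        out = response.normalize_amplitudes(self._amps([0.3]))
        assert out[0].normalized_pct == 100.0 and out[0].included

    def test_inclusion_needs_only_one_roi_over_threshold(self):
        amps = [ResponseAmplitude("a0", "ROI1", "odorX", 250.0, 0.29),
                ResponseAmplitude("a0", "ROI2", "odorX", 250.0, 0.31),
                ResponseAmplitude("a0", "ROI1", "ref", 250.0, 1.0)]
        out = response.normalize_amplitudes(amps)
        odorx = [a for a in out if a.odor_label == "odorX"]
        assert all(a.included for a in odorx)

    def test_exactly_one_amplitude_reaches_100(self, rng):
        raws = rng.uniform(0.01, 0.99, 10).tolist() + [1.0]
        out = response.normalize_amplitudes(self._amps(raws))
        assert sum(a.normalized_pct == 100.0 for a in out) == 1

    def test_all_zero_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            response.normalize_amplitudes(self._amps([0.0, 0.0]))


class TestActivationMap:
    def test_zero_dff_gives_zero_map(self, small_geometry):
        m = response.activation_map(_dff(np.zeros((40, 64, 80)), small_geometry))
        assert np.all(m.map == 0)

    def test_single_frame_window_returns_that_frame(self, small_geometry, rng):
        arr = rng.normal(size=(40, 64, 80))
        m = response.activation_map(_dff(arr, small_geometry),
                                    response_window=(12, 13))
        assert np.allclose(m.map, arr[12])

    def test_default_window_is_stimulus_plus_one_second(self, small_geometry):
        arr = np.zeros((40, 64, 80))
        arr[8:20] = 1.0  # exactly the default window
        m = response.activation_map(_dff(arr, small_geometry))
        assert np.allclose(m.map, 1.0)

    def test_map_maxima_at_ground_truth_centers(self, small_geometry):
        glomeruli = [synthgen.Glomerulus(20, 24, 20.0, {"stim": 0.06}),
                     synthgen.Glomerulus(44, 56, 20.0, {"stim": 0.05})]
        truth = synthgen.GroundTruthMovie(
            glomeruli=glomeruli, camera_offset=0.0, bleach_fraction=0.0,
            noise_sd=0.0)
        movie, _ = synthgen.generate_al_movie(truth, small_geometry, odor="stim")
        result = imaging.preprocess(movie, motion=False)
        m = response.activation_map(result.dff)
        peak = np.unravel_index(np.argmax(m.map), m.map.shape)
        assert abs(peak[0] - 20) <= 2 and abs(peak[1] - 24) <= 2


class TestPatternCorrelation:
    def test_identical_maps_correlate_perfectly(self, rng):
        arr = rng.normal(size=(30, 30))
        m = ActivationMap(arr, np.ones_like(arr, bool))
        assert response.pattern_correlation(m, m) == pytest.approx(1.0)

    def test_negated_map_correlates_minus_one(self, rng):
        arr = rng.normal(size=(30, 30))
        mask = np.ones_like(arr, bool)
        r = response.pattern_correlation(ActivationMap(arr, mask),
                                         ActivationMap(-arr, mask))
        assert r == pytest.approx(-1.0)

    def test_symmetry_and_scale_invariance(self, rng):
        a = rng.normal(size=(20, 20))
        b = rng.normal(size=(20, 20))
        mask = np.ones_like(a, bool)
        r_ab = response.pattern_correlation(ActivationMap(a, mask),
                                            ActivationMap(b, mask))
        r_ba = response.pattern_correlation(ActivationMap(b, mask),
                                            ActivationMap(a, mask))
        r_scaled = response.pattern_correlation(
            ActivationMap(a, mask), ActivationMap(3.0 * b + 2.0, mask))
        assert r_ab == pytest.approx(r_ba)
        assert r_ab == pytest.approx(r_scaled)

    def test_zero_variance_rejected(self):
        flat = ActivationMap(np.ones((10, 10)), np.ones((10, 10), bool))
        with pytest.raises(ValueError, match="variance"):
            response.pattern_correlation(flat, flat)


class TestRatioAndDisplay:
    @pytest.mark.parametrize("z, e, expected", [(2, 1, 2.0), (1, 1, 1.0),
                                                (1, 4, 0.25)])
    def test_activation_ratio(self, z, e, expected):
        assert response.roi_activation_ratio(z, e) == pytest.approx(expected)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            response.roi_activation_ratio(1.0, 0.0)

    @pytest.mark.parametrize("x, expected", [(1.0, 1.0), (0.5, -2.0),
                                             (5.0, 5.0), (0.2, -5.0)])
    def test_display_transform_values(self, x, expected):
        assert response.display_transform(x) == pytest.approx(expected)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            response.display_transform(0.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(min_value=1.0 + 1e-9, max_value=1e6))
    def test_reciprocal_antisymmetry(self, x):
        assert response.display_transform(1.0 / x) == \
            pytest.approx(-response.display_transform(x), rel=1e-9)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.floats(min_value=1e-6, max_value=1e6))
    def test_strictly_increasing_and_gap_excluded(self, x, y):
        tx, ty = response.display_transform(x), response.display_transform(y)
        assert abs(tx) >= 1.0
        if x < y:
            assert tx <= ty
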