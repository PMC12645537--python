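import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import myotrack as mt
from myotrack.profiles import detect_peaks, scanline_offsets


def brute_force_peaks(x, min_prominence, min_separation):
    """Independent oracle: enumerate local maxima (leftmost plateau sample),
    compute prominence by exhaustive scan, then greedy suppression by height
    (ties keep the leftmost)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    cands = []
    for i in range(1, n - 1):
        if x[i] <= x[i - 1]:
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j < n - 1 and x[j + 1] < x[i]:
            cands.append(i)
    keep = []
    for i in cands:
        h = x[i]
        left = [x[j] for j in range(i - 1, -1, -1)]
        lmin = h
        for v in left:
            if v > h:
                break
            lmin = min(lmin, v)
        rmin = h
        for v in x[i + 1 :]:
            if v > h:
                break
            rmin = min(rmin, v)
        if h - max(lmin, rmin) >= min_prominence:
            keep.append(i)
    result = []
    for i in sorted(keep, key=lambda i: (-x[i], i)):
        if all(abs(i - k) >= min_separation for k in result):
            result.append(i)
    return sorted(result)


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        frame = np.full((40, 60), 100.0)
        line = mt.TrackLine(id=0, kind="roi_horizontal", geometry=(5, 5, 50, 30))
        p = mt.extract_profile(frame, line, 0.0)
        assert len(p) == 50
        assert np.all(p.values == 100.0)

    def test_horizontal_line_matches_direct_indexing(self):
        frame = np.tile(np.arange(64.0), (32, 1))  # value == column index
        line = mt.TrackLine(id=0, kind="roi_horizontal", geometry=(3, 4, 40, 20))
        p = mt.extract_profile(frame, line, 7.0)
        assert np.allclose(p.values, np.arange(3, 43, dtype=float))

    def test_vertical_line_matches_direct_indexing(self):
        frame = np.tile(np.arange(48.0)[:, None], (1, 32))  # value == row index
        line = mt.TrackLine(id=0, kind="roi_vertical", geometry=(4, 6, 20, 30))
        p = mt.extract_profile(frame, line, 2.0)
        assert np.allclose(p.values, np.arange(6, 36, dtype=float))

    def test_diagonal_gradient_increases_by_cos45(self):
        frame = np.tile(np.arange(80.0), (80, 1))
        line = mt.TrackLine(id=0, kind="segment", geometry=(10, 10, 50, 50))
        p = mt.extract_profile(frame, line, 0.0)
        steps = np.diff(p.values)
        assert np.allclose(steps, math.cos(math.pi / 4), atol=1e-9)

    def test_profile_length_is_floor_length_plus_one(self):
        frame = np.zeros((64, 64))
        line = mt.TrackLine(id=0, kind="segment", geometry=(2, 2, 30.7, 2))
        p = mt.extract_profile(frame, line, 0.0)
        assert len(p) == int(math.floor(line.length)) + 1

    def test_offset_exits_frame_raises(self):
        frame = np.zeros((20, 64))
        line = mt.TrackLine(
            id=0, kind="segment", geometry=(5, 18, 50, 18), half_width=4
        )
        with pytest.raises(mt.ParameterError):
            mt.extract_profile(frame, line, 4.0)

    def test_roi_scanline_count_and_spacing(self):
        line = mt.TrackLine(
            id=0, kind="roi_horizontal", geometry=(0, 0, 50, 19), n_scanlines=10
        )
        offs = scanline_offsets(line)
        assert len(offs) == 10
        assert offs[0] == 0.0 and offs[-1] == 18.0
        assert np.allclose(np.diff(offs), 2.0)


class TestSmoothProfile:
    def test_window_one_is_identity(self, bf_profile):
        out = mt.smooth_profile(bf_profile, 1)
        assert np.array_equal(out.values, bf_profile.values)

    def test_constant_profile_unchanged(self):
        p = mt.IntensityProfile(np.full(32, 7.0), (0, 0), (1, 0))
        assert np.allclose(mt.smooth_profile(p, 5).values, 7.0)

    def test_unit_impulse_window3(self):
        vals = np.zeros(21)
        vals[10] = 1.0
        p = mt.IntensityProfile(vals, (0, 0), (1, 0))
        out = mt.smooth_profile(p, 3).values
        assert np.allclose(out[9:12], 1 / 3)
        assert np.allclose(np.delete(out, [9, 10, 11]), 0.0)

    @pytest.mark.parametrize("window", [2, 4, 17])
    def test_bad_window_rejected(self, window):
        p = mt.IntensityProfile(np.zeros(16), (0, 0), (1, 0))
        with pytest.raises(mt.ParameterError):
            mt.smooth_profile(p, window)

    def test_length_preserved(self, bf_profile):
        assert len(mt.smooth_profile(bf_profile, 7)) == len(bf_profile)


class TestDifferentiate:
    def test_linear_ramp_gives_constant_slope(self):
        p = mt.IntensityProfile(3.5 * np.arange(20.0), (0, 0), (1, 0))
        assert np.allclose(mt.differentiate(p), 3.5)

    def test_constant_gives_zeros(self):
        p = mt.IntensityProfile(np.full(12, 9.0), (0, 0), (1, 0))
        assert np.allclose(mt.differentiate(p), 0.0)

    def test_quadratic_exact_in_interior(self):
        x = np.arange(16.0)
        p = mt.IntensityProfile(x**2, (0, 0), (1, 0))
        d = mt.differentiate(p)
        assert np.allclose(d[1:-1], 2 * x[1:-1])

    def test_integrates_back_to_smoothed_profile(self, bf_profile):
        # the exact inverse of the central-difference operator is the
        # two-stride recurrence f[i+1] = f[i-1] + 2 d[i]; given the first
        # two samples it must reconstruct the smoothed profile exactly
        sp = mt.smooth_profile(bf_profile, 5)
        d = mt.differentiate(sp)
        recon = np.empty_like(sp.values)
        recon[0], recon[1] = sp.values[0], sp.values[1]
        for i in range(1, recon.size - 1):
            recon[i + 1] = recon[i - 1] + 2.0 * d[i]
        assert np.allclose(recon, sp.values, atol=1e-9)

    def test_cumsum_integrates_linear_ramp_exactly(self):
        p = mt.IntensityProfile(5.0 + 2.0 * np.arange(24.0), (0, 0), (1, 0))
        d = mt.differentiate(p)
        recon = p.values[0] + np.concatenate([[0.0], np.cumsum(d[1:])])
        assert np.allclose(recon, p.values, atol=1e-9)


class TestDetectPeaks:
    def test_single_apex(self):
        assert detect_peaks([0, 1, 0], min_prominence=0.5) == [1]

    def test_flat_signal_has_no_peaks(self):
        assert detect_peaks(np.full(16, 2.0)) == []

    def test_close_pair_keeps_taller(self):
        assert detect_peaks([0, 3, 0, 2, 0], min_separation=3) == [1]

    def test_plateau_reports_leftmost_sample(self):
        assert detect_peaks([0, 1, 1, 1, 0]) == [1]

    def test_tied_close_peaks_keep_leftmost(self):
        assert detect_peaks([0, 2, 0, 2, 0], min_separation=3) == [1]

    def test_prominence_filters_shallow_peak(self):
        # second bump only rises 0.5 above its saddle
        sig = [0, 3, 2.5, 3.0 - 1e-9, 0]
        assert detect_peaks(sig, min_prominence=1.0) == [1]

    @given(
        vals=st.lists(st.integers(0, 8), min_size=3, max_size=64),
        prom=st.integers(0, 4),
        sep=st.integers(1, 6),
    )
    def test_agrees_with_brute_force_oracle(self, vals, prom, sep):
        assert detect_peaks(vals, prom, sep) == brute_force_peaks(vals, prom, sep)

    def test_bad_parameters_rejected(self):
        with pytest.raises(mt.ParameterError):
            detect_peaks([0, 1, 0], min_prominence=-1)
        with pytest.raises(mt.ParameterError):
            detect_peaks([0, 1, 0], min_separation=0)
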