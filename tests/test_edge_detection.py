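import math

import numpy as np
import pytest

import myotrack as mt
from myotrack.edge_detection import DetectionParams, NoEdgesError


def gaussian_bands(centers, sigma=4.0, n=160, amplitude=1.0, offset=0.0):
    x = np.arange(float(n))
    vals = offset + sum(
        amplitude * np.exp(-((x - c) ** 2) / (2 * sigma**2)) for c in centers
    )
    return mt.IntensityProfile(np.asarray(vals), (0.0, 0.0), (1.0, 0.0))


class TestRefineSubpixel:
    def test_symmetric_peak_stays_at_index(self):
        assert mt.refine_subpixel(np.array([0.0, 1.0, 2.0, 1.0, 0.0]), 2) == 2.0

    def test_gaussian_center_recovered(self):
        x = np.arange(21.0)
        sig = np.exp(-((x - 10.3) ** 2) / (2 * 2.0**2))
        pos = mt.refine_subpixel(sig, int(np.argmax(sig)))
        assert pos == pytest.approx(10.3, abs=0.05)

    def test_zero_curvature_returns_index(self):
        assert mt.refine_subpixel(np.array([0.0, 1.0, 1.0, 1.0, 0.0]), 2) == 2.0

    def test_boundary_index_unchanged(self):
        sig = np.array([3.0, 1.0, 0.0])
        assert mt.refine_subpixel(sig, 0) == 0.0
        assert mt.refine_subpixel(sig, 2) == 2.0

    def test_vertex_clamped_to_half_sample(self):
        # strongly asymmetric neighbours cannot pull the vertex beyond 0.5
        sig = np.array([0.0, 10.0, 10.0 - 1e-9, 0.0])
        assert abs(mt.refine_subpixel(sig, 1) - 1) <= 0.5


class TestBrightfield:
    def test_piecewise_profile_edges_at_mid_transitions(self, bf_profile):
        es = mt.find_edges_brightfield(bf_profile)
        assert es.outer_left == pytest.approx(39.5, abs=0.6)
        assert es.inner_left == pytest.approx(51.5, abs=0.6)
        assert es.inner_right == pytest.approx(111.5, abs=0.6)
        assert es.outer_right == pytest.approx(123.5, abs=0.6)

    def test_flat_profile_raises(self):
        p = mt.IntensityProfile(np.full(64, 128.0), (0, 0), (1, 0))
        with pytest.raises(NoEdgesError):
            mt.find_edges_brightfield(p)

    def test_mirror_symmetric_profile_gives_symmetric_edges(self, bf_profile):
        es = mt.find_edges_brightfield(bf_profile)
        c = (len(bf_profile) - 1) / 2.0
        assert es.outer_left + es.outer_right == pytest.approx(2 * c, abs=1e-6)
        assert es.inner_left + es.inner_right == pytest.approx(2 * c, abs=1e-6)

    def test_wall_width_positive_and_ordered(self, bf_profile):
        es = mt.find_edges_brightfield(bf_profile)
        assert es.outer_left < es.inner_left < es.inner_right < es.outer_right


class TestFluorescence:
    def test_two_gaussian_bands(self):
        p = gaussian_bands([30.0, 130.0])
        es = mt.find_edges_fluorescence(p)
        assert es.outer_left < 30 < es.inner_left
        assert es.inner_right < 130 < es.outer_right
        # flank extrema sit at center +- sigma_eff, symmetric on both bands
        flank = 30.0 - es.outer_left
        assert es.outer_right - 130.0 == pytest.approx(flank, abs=0.2)
        assert es.outer_span() == pytest.approx(100.0 + 2 * flank, abs=0.2)

    def test_single_band_raises(self):
        with pytest.raises(NoEdgesError):
            mt.find_edges_fluorescence(gaussian_bands([80.0]))

    def test_uniform_offset_leaves_edges_unchanged(self):
        p0 = gaussian_bands([30.0, 130.0], amplitude=100.0)
        p1 = gaussian_bands([30.0, 130.0], amplitude=100.0, offset=50.0)
        e0 = mt.find_edges_fluorescence(p0)
        e1 = mt.find_edges_fluorescence(p1)
        for a, b in zip(
            (e0.outer_left, e0.inner_left, e0.inner_right, e0.outer_right),
            (e1.outer_left, e1.inner_left, e1.inner_right, e1.outer_right),
        ):
            assert a == pytest.approx(b, abs=1e-9)


class TestDispatch:
    def test_en_face_has_only_outer_edges(self):
        vals = np.concatenate([np.full(40, 200.0), np.full(40, 50.0), np.full(40, 200.0)])
        p = mt.IntensityProfile(vals, (0, 0), (1, 0))
        es = mt.find_edges(p, "en_face")
        assert es.mode == "en_face"
        assert not es.has_inner
        assert es.outer_left == pytest.approx(39.5, abs=0.6)
        assert es.outer_right == pytest.approx(79.5, abs=0.6)

    def test_ultrasound_matches_fluorescence(self):
        p = gaussian_bands([40.0, 120.0])
        eu = mt.find_edges(p, "ultrasound")
        ef = mt.find_edges_fluorescence(p)
        assert eu.outer_left == ef.outer_left
        assert eu.outer_right == ef.outer_right
        assert eu.mode == "ultrasound"

    def test_invert_flag_recovers_edges_of_negated_profile(self, bf_profile):
        neg = mt.IntensityProfile(-bf_profile.values, (0, 0), (1, 0))
        e_orig = mt.find_edges(bf_profile, "brightfield")
        e_inv = mt.find_edges(neg, "brightfield", DetectionParams(invert=True))
        assert e_inv.outer_left == pytest.approx(e_orig.outer_left, abs=1e-9)
        assert e_inv.outer_right == pytest.approx(e_orig.outer_right, abs=1e-9)

    def test_unknown_mode_rejected(self, bf_profile):
        with pytest.raises(mt.ParameterError):
            mt.find_edges(bf_profile, "darkfield")


def random_phantom_profile(rng):
    """Random brightfield-like profile: background, two walls, lumen,
    optically blurred as a real imaging system would."""
    from scipy.ndimage import gaussian_filter1d

    n = int(rng.integers(90, 180))
    od = rng.uniform(40, n - 30)
    wall = rng.uniform(6, max(7, od * 0.25))
    c = n / 2 + rng.uniform(-5, 5)
    bg = rng.uniform(150, 250)
    wl = rng.uniform(20, 80)
    lu = rng.uniform(wl + 40, bg)
    x = np.arange(float(n))
    d = np.abs(x - c)
    vals = np.where(d > od / 2, bg, np.where(d > od / 2 - wall, wl, lu))
    vals = gaussian_filter1d(vals, rng.uniform(0.6, 1.5))
    return mt.IntensityProfile(vals, (0.0, 0.0), (1.0, 0.0)), c, od


class TestInvariances:
    def test_ordering_scale_translation_over_random_profiles(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(300):
            p, c, od = random_phantom_profile(rng)
            try:
                es = mt.find_edges_brightfield(p)
            except NoEdgesError:
                continue
            checked += 1
            assert es.outer_left < es.outer_right
            if es.has_inner:
                assert es.outer_left < es.inner_left < es.inner_right < es.outer_right
            # intensity scaling leaves edges unchanged
            ps = mt.IntensityProfile(p.values * 3.7, p.origin, p.direction)
            ess = mt.find_edges_brightfield(ps)
            assert ess.outer_left == pytest.approx(es.outer_left, abs=1e-9)
            assert ess.outer_right == pytest.approx(es.outer_right, abs=1e-9)
            # translation by whole samples shifts edges exactly
            s = 7
            pt = mt.IntensityProfile(
                np.concatenate([np.full(s, p.values[0]), p.values]),
                p.origin,
                p.direction,
            )
            est = mt.find_edges_brightfield(pt)
            assert est.outer_left == pytest.approx(es.outer_left + s, abs=1e-9)
            assert est.outer_right == pytest.approx(es.outer_right + s, abs=1e-9)
        assert checked > 200

    def test_noise_robustness_half_pixel_rms(self, bf_profile):
        """At 5%-of-range additive noise, edges on the standard phantom
        profile (optical PSF sigma 0.8 px) stay within 0.5 px RMS."""
        from scipy.ndimage import gaussian_filter1d

        vals = gaussian_filter1d(bf_profile.values, 0.8)
        blurred = mt.IntensityProfile(vals, bf_profile.origin, bf_profile.direction)
        truth = mt.find_edges_brightfield(blurred)
        rng = np.random.default_rng(11)
        sd = 0.05 * (vals.max() - vals.min())
        errs = []
        for _ in range(200):
            noisy = mt.IntensityProfile(
                vals + rng.normal(0, sd, vals.size),
                blurred.origin,
                blurred.direction,
            )
            try:
                es = mt.find_edges_brightfield(noisy)
            except NoEdgesError:
                continue
            errs.append(es.outer_left - truth.outer_left)
            errs.append(es.outer_right - truth.outer_right)
        assert len(errs) > 300
        assert float(np.sqrt(np.mean(np.square(errs)))) < 0.5


class TestEdgeSetInvariants:
    def test_out_of_order_outer_edges_rejected(self):
        with pytest.raises(NoEdgesError):
            mt.EdgeSet(outer_left=10.0, outer_right=5.0)

    def test_inner_edges_must_come_in_pairs(self):
        with pytest.raises(NoEdgesError):
            mt.EdgeSet(outer_left=0.0, outer_right=10.0, inner_left=3.0)

    def test_en_face_never_carries_inner_edges(self):
        with pytest.raises(NoEdgesError):
            mt.EdgeSet(
                outer_left=0.0,
                outer_right=10.0,
                inner_left=3.0,
                inner_right=7.0,
                mode="en_face",
            )
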