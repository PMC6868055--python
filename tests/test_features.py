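"""Foci detection and the 13-feature extraction."""

import numpy as np
import pytest

from kinetoforge import (FEATURE_NAMES, augment_orientations, detect_foci,
                         distances, extract_features, linescan_std,
                         region_stats, spindle_axis, spot_height)
from kinetoforge.features import Focus, GREEN, RED

from conftest import make_spot_image


def focus_at(r, c, peak=1000.0, channel="green"):
    return Focus(int(round(r)), int(round(c)), float(r), float(c), peak, channel)


class TestDetectFoci:
    def test_subpixel_accuracy_at_snr_20(self):
        img = make_spot_image(centers_green=[(24.6, 17.3), (25.4, 32.8)],
                              centers_red=[], sigma=1.5, amp=40000.0,
                              noise_sd=2000.0, seed=1)
        foci = detect_foci(img, GREEN, 2)
        assert len(foci) == 2
        found = sorted((f.sub_row, f.sub_col) for f in foci)
        truth = sorted([(24.6, 17.3), (25.4, 32.8)])
        for (fr, fc), (tr, tc) in zip(found, truth):
            assert abs(fr - tr) < 0.25 and abs(fc - tc) < 0.25

    def test_blank_image_yields_no_foci(self):
        img = np.zeros((50, 50, 3), dtype=np.uint16)
        assert detect_foci(img, GREEN, 2) == []

    def test_single_spot_cannot_satisfy_two_expected(self):
        img = make_spot_image(centers_green=[(25.0, 25.0)], centers_red=[],
                              noise_sd=500.0, seed=2)
        assert len(detect_foci(img, GREEN, 2)) == 1

    def test_foci_sorted_left_to_right(self, spot_image):
        foci = detect_foci(spot_image, RED, 2)
        assert foci[0].col < foci[1].col


class TestSpindleAxis:
    def test_horizontal_axis_length(self):
        axis, length = spindle_axis([focus_at(25, 10), focus_at(25, 40)])
        assert length == pytest.approx(30.0)
        np.testing.assert_allclose(np.abs(axis), [0.0, 1.0])

    def test_three_four_five_triangle(self):
        _, length = spindle_axis([focus_at(10, 10), focus_at(13, 14)])
        assert length == pytest.approx(5.0)

    def test_axis_sign_invariance_under_swap(self):
        a, _ = spindle_axis([focus_at(10, 10), focus_at(13, 14)])
        b, _ = spindle_axis([focus_at(13, 14), focus_at(10, 10)])
        np.testing.assert_allclose(np.abs(a), np.abs(b))

    def test_coincident_spbs_are_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            spindle_axis([focus_at(25, 25), focus_at(25, 25)])


class TestSpotHeight:
    def gaussian_spot(self, sigma):
        return make_spot_image(centers_green=[(25.0, 25.0)], centers_red=[],
                               sigma=sigma, amp=40000.0, noise_sd=0.0)

    def test_fwhm_of_sigma2_profile(self):
        img = self.gaussian_spot(sigma=2.0)
        h = spot_height(img, focus_at(25, 25), np.array([0.0, 1.0]),
                        channel=GREEN)
        assert h == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 2.0, rel=0.05)

    def test_amplitude_invariance(self):
        img = self.gaussian_spot(sigma=2.0).astype(float)
        axis = np.array([0.0, 1.0])
        h1 = spot_height(img, focus_at(25, 25), axis, channel=GREEN)
        h2 = spot_height(img / 2.0, focus_at(25, 25), axis, channel=GREEN)
        assert h1 == pytest.approx(h2, rel=1e-6)

    def test_near_edge_flagged(self):
        img = self.gaussian_spot(sigma=2.0)
        assert spot_height(img, focus_at(2, 25), np.array([0.0, 1.0]),
                           channel=GREEN) is None


class TestLinescanStd:
    def test_constant_image_scans_to_zero(self):
        img = np.full((50, 50, 3), 500, dtype=np.uint16)
        v = linescan_std(img, focus_at(25, 25), "parallel",
                         np.array([0.0, 1.0]), channel=GREEN)
        assert v == pytest.approx(0.0, abs=1e-9)

    def test_direction_swaps_under_transpose(self):
        img = make_spot_image(centers_green=[(25.0, 25.0)], centers_red=[],
                              sigma=1.2, noise_sd=0.0)
        img = img.astype(float)
        img[..., 1] *= np.linspace(0.5, 1.5, 50)[None, :]  # anisotropy
        axis = np.array([0.0, 1.0])
        par = linescan_std(img, focus_at(25, 25), "parallel", axis, channel=GREEN)
        per_t = linescan_std(img.transpose(1, 0, 2), focus_at(25, 25),
                             "perpendicular", axis, channel=GREEN)
        assert par == pytest.approx(per_t, rel=1e-6)

    def test_isotropic_spot_is_direction_symmetric(self):
        img = make_spot_image(centers_green=[(25.0, 25.0)], centers_red=[],
                              sigma=1.5, noise_sd=0.0)
        axis = np.array([0.0, 1.0])
        par = linescan_std(img, focus_at(25, 25), "parallel", axis, channel=GREEN)
        per = linescan_std(img, focus_at(25, 25), "perpendicular", axis,
                           channel=GREEN)
        assert par == pytest.approx(per, rel=0.1)


class TestRegionStats:
    def test_constant_region(self):
        img = np.full((50, 50, 3), 100, dtype=np.uint16)
        mean, std = region_stats(img, focus_at(25, 25), channel=GREEN)
        assert (mean, std) == (100.0, 0.0)

    def test_hand_built_block(self):
        img = np.zeros((50, 50, 3))
        block = np.arange(25.0).reshape(5, 5)
        img[23:28, 23:28, 1] = block
        mean, std = region_stats(img, focus_at(25, 25), channel=GREEN)
        assert mean == pytest.approx(block.mean())
        assert std == pytest.approx(block.std(ddof=1))

    def test_mean_invariant_under_d4(self):
        # odd-sized image: the window about the center maps onto itself
        rng = np.random.default_rng(8)
        img = rng.integers(0, 1000, size=(49, 49, 3)).astype(np.uint16)
        means = {region_stats(o, focus_at(24, 24), channel=GREEN)[0]
                 for o in augment_orientations(img)}
        assert max(means) - min(means) < 1e-9

    def test_off_image_window_flagged(self):
        img = np.zeros((50, 50, 3), dtype=np.uint16)
        assert region_stats(img, focus_at(1, 25), channel=GREEN) is None


class TestDistances:
    axis = np.array([0.0, 1.0])

    def test_kinetochore_at_midpoint(self):
        spb = [focus_at(25, 10, channel="red"), focus_at(25, 40, channel="red")]
        k = [focus_at(25, 25), focus_at(25, 25)]
        kk, d_spb, d_x = distances(k, spb, self.axis, 30.0)
        assert d_spb == pytest.approx(0.5)

    def test_kinetochore_coincident_with_spb(self):
        spb = [focus_at(25, 10), focus_at(25, 40)]
        k = [focus_at(25, 10), focus_at(25, 40)]
        kk, d_spb, d_x = distances(k, spb, self.axis, 30.0)
        assert d_spb == 0.0 and d_x == 0.0

    def test_pure_perpendicular_displacement(self):
        spb = [focus_at(25, 10), focus_at(25, 40)]
        k = [focus_at(28, 10), focus_at(22, 40)]
        kk, d_spb, d_x = distances(k, spb, self.axis, 30.0)
        assert d_x == pytest.approx(0.0, abs=1e-9)
        assert d_spb == pytest.approx(3.0 / 30.0)


class TestExtractFeatures:
    def test_known_geometry_recovered(self, spot_image):
        rec, flag = extract_features(spot_image)
        assert flag is None
        vals = rec.as_array()
        assert np.isfinite(vals).all()
        # K at (25,20),(25,30); SPB at (25,10),(25,40): spindle length 30
        assert rec.kk_distance == pytest.approx(10 / 30, abs=0.05)
        assert rec.kinetochore_distance_to_spb == pytest.approx(10 / 30, abs=0.05)
        assert rec.kinetochore_x_distance == pytest.approx(10 / 30, abs=0.05)

    def test_missing_spb_flags_image(self):
        img = make_spot_image(centers_green=[(25.0, 20.0), (25.0, 30.0)],
                              centers_red=[(25.0, 10.0)], noise_sd=500.0,
                              seed=3)
        rec, flag = extract_features(img)
        assert rec is None and "SPB" in flag

    def test_extraction_is_deterministic(self, spot_image):
        a, _ = extract_features(spot_image)
        b, _ = extract_features(spot_image)
        np.testing.assert_array_equal(a.as_array(), b.as_array())

    def test_distance_features_stable_under_d4(self, spot_image):
        invariant = ["kinetochore_distance_to_spb", "kinetochore_x_distance",
                     "kk_distance", "spb_height", "kinetochore_height"]
        records = []
        for oriented in augment_orientations(spot_image):
            rec, flag = extract_features(oriented)
            assert flag is None
            records.append(rec)
        for name in invariant:
            vals = [getattr(r, name) for r in records]
            ref = np.mean(vals)
            assert max(abs(v - ref) for v in vals) < 0.1 * max(abs(ref), 1.0)

    def test_feature_names_match_record_order(self):
        assert len(FEATURE_NAMES) == 13
        assert FEATURE_NAMES[0] == "kinetochore_distance_to_spb"
        assert FEATURE_NAMES[10] == "kk_distance"
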