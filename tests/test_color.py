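"""Colour conversion, ΔE76 and contrast scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimevo.color import (
    BackgroundSet,
    LabColour,
    RGBColour,
    delta_e_76,
    external_contrast,
    fit_calibration,
    internal_contrast,
    lab_array_from_srgb,
    sample_patch,
    srgb_to_lab,
)


class TestSrgbToLab:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((1.0, 1.0, 1.0), (100.0, 0.0, 0.0)),
            ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
            # independent reference colorimetry value for pure sRGB red
            ((1.0, 0.0, 0.0), (53.2406, 80.0924, 67.2032)),
        ],
    )
    def test_reference_colours(self, rgb, expected):
        lab = srgb_to_lab(RGBColour(*rgb))
        assert lab.L == pytest.approx(expected[0], abs=1e-3)
        assert lab.a == pytest.approx(expected[1], abs=1e-3)
        assert lab.b == pytest.approx(expected[2], abs=1e-3)

    def test_white_maps_exactly_to_reference_white(self):
        lab = srgb_to_lab(RGBColour(1.0, 1.0, 1.0))
        assert abs(lab.a) < 1e-6 and abs(lab.b) < 1e-6

    def test_out_of_gamut_channel_rejected(self):
        with pytest.raises(ValueError):
            RGBColour(1.2, 0.0, 0.0)

    def test_agrees_with_reference_implementation(self, rng):
        skcolor = pytest.importorskip("skimage.color")
        panel = rng.uniform(0.0, 1.0, size=(100, 3))
        mine = lab_array_from_srgb(panel)
        ref = skcolor.rgb2lab(panel.reshape(1, -1, 3)).reshape(-1, 3)
        assert np.linalg.norm(mine - ref, axis=1).max() < 0.01

    def test_linear_rgb_tag_skips_companding(self):
        gamma = srgb_to_lab(RGBColour(0.5, 0.5, 0.5, "sRGB_gamma"))
        linear = srgb_to_lab(RGBColour(0.5, 0.5, 0.5, "linear_RGB"))
        assert linear.L > gamma.L  # companding darkens mid greys


class TestDeltaE:
    @pytest.mark.parametrize(
        "c1, c2, expected",
        [
            ((50, 10, -5), (50, 10, -5), 0.0),
            ((0, 0, 0), (100, 0, 0), 100.0),
            ((50, 20, -30), (60, -10, 40), np.sqrt(5900)),
        ],
    )
    def test_examples(self, c1, c2, expected):
        assert delta_e_76(LabColour(*c1), LabColour(*c2)) == pytest.approx(expected)

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100), st.floats(-120, 120), st.floats(-120, 120)
            ),
            min_size=3,
            max_size=3,
        )
    )
    def test_metric_axioms(self, triple):
        a, b, c = (LabColour(*t) for t in triple)
        dab, dba = delta_e_76(a, b), delta_e_76(b, a)
        assert dab >= 0 and dab == pytest.approx(dba)
        assert delta_e_76(a, a) == 0
        assert delta_e_76(a, c) <= dab + delta_e_76(b, c) + 1e-9


class TestSamplePatch:
    def test_constant_image_recovers_colour(self):
        img = np.full((64, 64, 3), 0.4)
        ps = sample_patch(img, [(20, 20), (30, 30), (20, 40), (40, 20), (32, 32)], 31)
        expected = lab_array_from_srgb(np.array([0.4, 0.4, 0.4]))
        assert np.allclose(ps.mean.as_array(), expected, atol=1e-9)
        assert len(ps.replicate_means) == 5

    def test_two_half_image_windows_in_one_half(self):
        img = np.zeros((80, 160, 3))
        img[:, 80:, :] = [0.9, 0.1, 0.1]
        centres = [(40, 100), (30, 110), (50, 120), (40, 130), (40, 140)]
        ps = sample_patch(img, centres, 31)
        expected = lab_array_from_srgb(np.array([0.9, 0.1, 0.1]))
        assert np.allclose(ps.mean.as_array(), expected, atol=1e-9)

    def test_noisy_patch_mean_close_to_truth(self, rng):
        base = np.array([0.7, 0.4, 0.2])
        img = np.clip(base + rng.normal(0, 0.01, size=(64, 64, 3)), 0, 1)
        ps = sample_patch(img, [(20, 20), (30, 30), (20, 40), (40, 20), (32, 32)], 31)
        truth = lab_array_from_srgb(base)
        assert np.linalg.norm(ps.mean.as_array() - truth) < 1.0

    def test_border_clipping_names_offending_centre(self):
        img = np.zeros((40, 40, 3))
        with pytest.raises(ValueError, match=r"\(2, 20\)"):
            sample_patch(img, [(2, 20)], 31)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            sample_patch(np.zeros((40, 40, 3)), [(20, 20)], 30)

    def test_uint8_and_float_agree(self):
        img8 = np.full((40, 40, 3), 102, dtype=np.uint8)
        imgf = np.full((40, 40, 3), 102 / 255.0)
        p8 = sample_patch(img8, [(20, 20)], 11)
        pf = sample_patch(imgf, [(20, 20)], 11)
        assert np.allclose(p8.mean.as_array(), pf.mean.as_array(), atol=1e-9)


class TestContrast:
    def _backgrounds(self):
        entries = {
            ("leaf1", "upper"): LabColour(46.2, -51.7, 49.9),
            ("leaf1", "bottom"): LabColour(70.0, -30.0, 40.0),
            ("leaf2", "upper"): LabColour(30.0, -40.0, 30.0),
            ("leaf2", "bottom"): LabColour(60.0, -25.0, 35.0),
            ("leaf3", "upper"): LabColour(55.0, -45.0, 45.0),
            ("leaf3", "bottom"): LabColour(75.0, -20.0, 38.0),
        }
        return BackgroundSet(entries=entries)

    def test_six_backgrounds_give_six_values_per_part(self):
        profile = external_contrast(LabColour(53.2, 80.1, 67.2), None, self._backgrounds())
        assert len(profile.ec_upper) + len(profile.ec_bottom) == 6

    def test_part_equal_to_background_scores_zero(self):
        bg = self._backgrounds()
        profile = external_contrast(LabColour(46.2, -51.7, 49.9), None, bg)
        assert profile.ec_upper[("bright", "leaf1")] == pytest.approx(0.0)

    def test_hand_computed_value(self):
        profile = external_contrast(
            LabColour(53.2, 80.1, 67.2), None, self._backgrounds()
        )
        # hand evaluation: sqrt(7^2 + 131.8^2 + 17.3^2)
        expected = np.sqrt(49 + 17371.24 + 299.29)
        assert profile.ec_upper[("bright", "leaf1")] == pytest.approx(expected, abs=1e-9)

    def test_background_insertion_order_irrelevant(self):
        bg1 = self._backgrounds()
        entries = dict(reversed(list(bg1.entries.items())))
        bg2 = BackgroundSet(entries=entries)
        bright = LabColour(60, 40, 30)
        p1 = external_contrast(bright, None, bg1)
        p2 = external_contrast(bright, None, bg2)
        assert p1.ec_upper == p2.ec_upper and p1.ec_bottom == p2.ec_bottom

    def test_empty_background_set_rejected(self):
        with pytest.raises(ValueError):
            external_contrast(LabColour(50, 0, 0), None, BackgroundSet(entries={}))

    def test_internal_contrast_is_delta_e(self):
        b, d = LabColour(70, 30, 50), LabColour(20, 5, 5)
        assert internal_contrast(b, d) == pytest.approx(delta_e_76(b, d))
        assert internal_contrast(b, b) == 0.0
        with pytest.raises(ValueError):
            internal_contrast(b, None)


class TestCalibration:
    def _colours(self, arr):
        return [RGBColour(*np.clip(row, 0, 1), colour_space="linear_RGB") for row in arr]

    def test_identity_when_measured_equals_reference(self, rng):
        vals = rng.uniform(0.1, 0.9, size=(8, 3))
        fit = fit_calibration(self._colours(vals), self._colours(vals))
        assert np.allclose(fit.matrix, np.eye(3), atol=1e-9)
        assert np.allclose(fit.offset, 0, atol=1e-9)
        assert fit.fit_residual == pytest.approx(0, abs=1e-12)

    def test_exact_inverse_scaling(self, rng):
        ref = rng.uniform(0.1, 0.9, size=(8, 3))
        fit = fit_calibration(self._colours(ref * 0.5), self._colours(ref))
        assert np.allclose(fit.matrix, 2 * np.eye(3), atol=1e-9)
        assert fit.fit_residual == pytest.approx(0, abs=1e-12)

    def test_recovers_known_affine_map_under_noise(self, rng):
        true_m = np.array([[0.9, 0.05, 0.0], [0.02, 1.1, 0.03], [0.0, 0.04, 0.95]])
        true_off = np.array([0.02, -0.01, 0.03])
        meas = rng.uniform(0.1, 0.8, size=(24, 3))
        ref = meas @ true_m.T + true_off + rng.normal(0, 0.005, size=(24, 3))
        fit = fit_calibration(self._colours(meas), self._colours(np.clip(ref, 0, 1)))
        assert np.abs(fit.matrix - true_m).max() < 0.05

    def test_too_few_pairs_rejected(self, rng):
        vals = rng.uniform(0.2, 0.8, size=(3, 3))
        with pytest.raises(ValueError):
            fit_calibration(self._colours(vals), self._colours(vals))
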