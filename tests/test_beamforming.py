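"""DAS localization, SLSC coherence values, masks and Dice."""

import numpy as np
import pytest

from paatlas.beamforming import (
    CoherenceMask,
    _select_best,
    aligned_channel_cube,
    combine_lag_images,
    das_image,
    dice,
    lag_coherence_images,
    make_mask,
    merge_masks,
    mweighted_slsc_image,
    select_M,
    slsc_image,
    triangular_lag_weights,
)
from paatlas.core_io import AcquisitionGeometry, BeamformedImage, ChannelFrame

from conftest import single_point_frame


def _coh(pixels, spacing=0.1):
    return BeamformedImage(
        pixels=np.asarray(pixels, dtype=float),
        kind="coherence",
        axial_spacing_mm=spacing,
        lateral_spacing_mm=spacing,
    )


class TestDAS:
    def test_point_source_localized_within_one_pixel(self, tiny_geom):
        z, x = 9.0, 4.5
        frame = single_point_frame(tiny_geom, z, x)
        img = das_image(frame, tiny_geom)
        i, j = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        assert abs(i * tiny_geom.axial_spacing_mm - z) <= tiny_geom.axial_spacing_mm
        assert abs(j * tiny_geom.lateral_spacing_mm - x) <= tiny_geom.lateral_spacing_mm

    def test_zero_input_gives_zero_image(self, tiny_geom):
        frame = ChannelFrame(
            rf=np.zeros((100, tiny_geom.n_elements)), optical_wavelength=710
        )
        img = das_image(frame, tiny_geom)
        assert not np.any(img.pixels)

    def test_two_equal_sources_have_equal_peaks(self, tiny_geom):
        # mirrored about the aperture center -> symmetric forward model
        center = tiny_geom.aperture_mm / 2
        f1 = single_point_frame(tiny_geom, 8.0, center - 2.0)
        f2 = single_point_frame(tiny_geom, 8.0, center + 2.0)
        frame = ChannelFrame(rf=f1.rf + f2.rf, optical_wavelength=710)
        img = das_image(frame, tiny_geom).pixels
        i = int(round(8.0 / tiny_geom.axial_spacing_mm))
        j1 = int(round((center - 2.0) / tiny_geom.lateral_spacing_mm))
        j2 = int(round((center + 2.0) / tiny_geom.lateral_spacing_mm))
        p1 = img[i - 2 : i + 3, j1 - 1 : j1 + 2].max()
        p2 = img[i - 2 : i + 3, j2 - 1 : j2 + 2].max()
        assert p1 == pytest.approx(p2, rel=0.01)

    def test_grid_deeper_than_recording_rejected(self, tiny_geom):
        frame = ChannelFrame(
            rf=np.zeros((50, tiny_geom.n_elements)), optical_wavelength=710
        )
        with pytest.raises(ValueError, match="deeper"):
            das_image(frame, tiny_geom, n_rows=1000)


class TestSLSC:
    def test_identical_channels_give_unit_coherence(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=(120, 1, 1))
        cube = np.broadcast_to(sig, (120, 6, 16)).astype(np.float32).copy()
        lags = lag_coherence_images(cube, M=5, corr_kernel=9)
        np.testing.assert_allclose(lags, 1.0, atol=1e-6)

    def test_independent_noise_coherence_near_zero(self):
        rng = np.random.default_rng(1)
        cube = rng.normal(size=(200, 10, 32)).astype(np.float32)
        img = combine_lag_images(lag_coherence_images(cube, M=5, corr_kernel=16))
        assert img.size >= 1000
        assert abs(img.mean()) < 0.05

    def test_single_lag_equals_m1_image(self, tiny_geom):
        frame = single_point_frame(tiny_geom, 8.0, 4.0)
        img = slsc_image(frame, tiny_geom, M=1, corr_kernel=8)
        lags = lag_coherence_images(
            aligned_channel_cube(frame, tiny_geom), M=1, corr_kernel=8
        )
        np.testing.assert_allclose(img.pixels, lags[0], atol=1e-9)

    def test_numba_and_numpy_engines_agree(self):
        rng = np.random.default_rng(2)
        cube = rng.normal(size=(80, 12, 16)).astype(np.float32)
        a = lag_coherence_images(cube, M=6, corr_kernel=5, engine="numpy")
        b = lag_coherence_images(cube, M=6, corr_kernel=5, engine="numba")
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_uniform_weights_reduce_to_normalized_slsc(self, tiny_geom):
        frame = single_point_frame(tiny_geom, 8.0, 5.0)
        plain = slsc_image(frame, tiny_geom, M=6, corr_kernel=8)
        weighted = mweighted_slsc_image(
            frame, tiny_geom, M=6, corr_kernel=8, weights=np.ones(6)
        )
        np.testing.assert_allclose(weighted.pixels, plain.pixels, atol=1e-9)

    def test_triangular_weighting_hand_value(self):
        # c_hat = [1, 0, 0] with weights [3, 2, 1] -> 3/6 = 0.5
        lags = np.stack([np.ones((4, 4)), np.zeros((4, 4)), np.zeros((4, 4))])
        out = combine_lag_images(lags, triangular_lag_weights(3))
        np.testing.assert_allclose(out, 0.5)

    def test_invalid_lag_count_rejected(self, tiny_geom):
        frame = single_point_frame(tiny_geom, 8.0, 5.0)
        with pytest.raises(ValueError, match="M must"):
            slsc_image(frame, tiny_geom, M=tiny_geom.n_elements)

    def test_coherent_target_exceeds_background(self, tiny_geom):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            frame = single_point_frame(tiny_geom, 8.0, 4.5)
            noisy = ChannelFrame(
                rf=frame.rf + 0.05 * rng.normal(size=frame.rf.shape),
                optical_wavelength=710,
            )
            coh = mweighted_slsc_image(noisy, tiny_geom, M=8).pixels
            i = int(round(8.0 / tiny_geom.axial_spacing_mm))
            j = int(round(4.5 / tiny_geom.lateral_spacing_mm))
            target = coh[i - 3 : i + 4, j - 2 : j + 3].mean()
            background = coh[: i - 20].mean()
            assert target > background


class TestMasks:
    def test_db_mode_keeps_constant_image(self):
        m = make_mask(_coh(np.full((5, 5), 0.4)), "db", -3.0)
        assert m.mask.all()

    def test_absolute_mode_direct_comparison(self):
        m = make_mask(_coh([[0.9, 0.6, 0.2]]), "absolute", 0.7)
        np.testing.assert_array_equal(m.mask, [[True, False, False]])

    def test_higher_threshold_is_subset(self):
        img = _coh(np.random.default_rng(5).random((20, 20)))
        lo = make_mask(img, "absolute", 0.32)
        hi = make_mask(img, "absolute", 0.70)
        assert np.all(~hi.mask | lo.mask)

    def test_area_nonincreasing_in_threshold(self):
        img = _coh(np.random.default_rng(6).random((30, 30)))
        thresholds = np.round(np.arange(0.3, 0.9 + 1e-9, 0.02), 2)
        areas = [make_mask(img, "absolute", t).area for t in thresholds]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_absolute_threshold_range_checked(self):
        with pytest.raises(ValueError):
            make_mask(_coh(np.ones((2, 2))), "absolute", 1.5)

    def test_amplitude_image_rejected(self):
        img = BeamformedImage(
            pixels=np.ones((2, 2)), kind="amplitude",
            axial_spacing_mm=0.1, lateral_spacing_mm=0.1,
        )
        with pytest.raises(ValueError, match="coherence"):
            make_mask(img)

    def test_merge_is_inclusive_or(self):
        a = CoherenceMask(np.array([[True, False]]), "absolute", 0.7)
        b = CoherenceMask(np.array([[False, True]]), "absolute", 0.7)
        assert merge_masks([a]).mask.tolist() == a.mask.tolist()
        assert merge_masks([a, b]).mask.all()
        falses = [
            CoherenceMask(np.zeros((1, 2), bool), "absolute", 0.7)
            for _ in range(20)
        ]
        assert not merge_masks(falses).mask.any()

    def test_merge_rejects_mismatched_shapes(self):
        a = CoherenceMask(np.zeros((2, 2), bool), "absolute", 0.7)
        b = CoherenceMask(np.zeros((3, 2), bool), "absolute", 0.7)
        with pytest.raises(ValueError):
            merge_masks([a, b])


class TestDice:
    def _m(self, arr):
        return CoherenceMask(np.array(arr, dtype=bool), "absolute", 0.7)

    def test_identical_masks_score_100(self):
        a = self._m([[1, 1, 0]])
        assert dice(a, a) == 100.0

    def test_disjoint_masks_score_0(self):
        assert dice(self._m([[1, 0]]), self._m([[0, 1]])) == 0.0

    def test_hand_counted_overlap(self):
        # |a| = 4, |b| = 6, overlap 3 -> 2*3/10 * 100 = 60%
        a = self._m([[1, 1, 1, 1, 0, 0, 0, 0, 0]])
        b = self._m([[0, 1, 1, 1, 1, 1, 1, 0, 0]])
        assert dice(a, b) == pytest.approx(60.0)
        assert dice(b, a) == dice(a, b)

    def test_both_empty_is_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            dice(self._m([[0, 0]]), self._m([[0, 0]]))


class TestSelectM:
    def test_single_candidate_returned(self, tiny_geom):
        frame = single_point_frame(tiny_geom, 8.0, 4.5)
        assert select_M([frame], tiny_geom, [12]) == 12

    def test_tie_breaks_prefer_low_sd_then_low_m(self):
        assert _select_best([10, 20], [90.0, 90.0], [5.0, 1.0]) == 20
        assert _select_best([10, 20], [90.0, 90.0], [2.0, 2.0]) == 10
        assert _select_best([10, 20], [80.0, 95.0], [0.1, 9.0]) == 20

    def test_empty_inputs_rejected(self, tiny_geom):
        with pytest.raises(ValueError):
            select_M([], tiny_geom, [10, 20])
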