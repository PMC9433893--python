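"""Mixture estimator: pairwise regression closure, histogram filter,
median reduction and map estimation."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paatlas.atlas_estimator import (
    Atlas,
    EstimatorConfig,
    beamform_trial,
    build_atlas,
    concentration_distribution,
    estimate_map,
    histogram_filter,
    load_atlas,
    median_filter_tensor,
    parameter_sweep,
    save_atlas,
    threshold_sweep,
    trial_mask,
)
from paatlas.spectral_features import FeatureMatrix

from conftest import make_tiny_trial


def _point_atlas(hb_value, mb_value, p=1, cfg=None):
    """Atlas whose classes are single points in feature space."""
    basis = np.eye(max(p, 2))[:, :p]
    fm = FeatureMatrix(
        basis=basis,
        mean_spectrum=np.zeros(max(p, 2)),
        projected=np.zeros((2, p)),
        p=p,
    )
    return Atlas(
        fm=fm,
        mb_rows=np.full((5, p), mb_value, dtype=float),
        hb_rows=np.full((5, p), hb_value, dtype=float),
        config=cfg or EstimatorConfig(),
    )


class TestMixtureEstimator:
    def test_linear_mixtures_recovered_exactly_on_a_grid(self):
        """Brute-force closure: x = (1-c) b + c a -> C' = c for every draw."""
        a, b = 7.0, -3.0  # MB and Hb anchors
        atlas = _point_atlas(hb_value=b, mb_value=a)
        for c in np.linspace(0.0, 1.0, 101):
            x = np.array([(1 - c) * b + c * a])
            cprime = concentration_distribution(x, atlas, n_draws=20, rng=0)
            np.testing.assert_allclose(cprime, c, atol=1e-12)

    def test_pure_class_features_map_to_endpoints(self):
        atlas = _point_atlas(hb_value=2.0, mb_value=9.0)
        np.testing.assert_allclose(
            concentration_distribution(np.array([2.0]), atlas, 50, 1), 0.0
        )
        np.testing.assert_allclose(
            concentration_distribution(np.array([9.0]), atlas, 50, 1), 1.0
        )

    def test_scalar_hand_values_and_clamp(self):
        atlas = _point_atlas(hb_value=0.0, mb_value=10.0)
        np.testing.assert_allclose(
            concentration_distribution(np.array([6.0]), atlas, 30, 2), 0.6
        )
        # x = 15: 1/2 + (15 - 5)/20 = 1 exactly at the clamp boundary
        np.testing.assert_allclose(
            concentration_distribution(np.array([15.0]), atlas, 30, 2), 1.0
        )
        # far outside: clamped
        np.testing.assert_allclose(
            concentration_distribution(np.array([99.0]), atlas, 30, 2), 1.0
        )
        np.testing.assert_allclose(
            concentration_distribution(np.array([-99.0]), atlas, 30, 2), 0.0
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(-1e6, 1e6, allow_nan=False),
        st.floats(-50, 50),
        st.floats(-50, 50),
    )
    def test_clamp_property_for_arbitrary_inputs(self, x, hb, mb):
        rng = np.random.default_rng(0)
        atlas = _point_atlas(
            hb_value=hb, mb_value=mb + 1e-3
        )  # distinct classes
        out = concentration_distribution(np.array([x]), atlas, 25, rng)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_fully_degenerate_atlas_errors_after_redraws(self):
        atlas = _point_atlas(hb_value=4.0, mb_value=4.0)
        with pytest.raises(ValueError, match="degenerate"):
            concentration_distribution(np.array([1.0]), atlas, 10, 0)


class TestHistogramFilter:
    def test_constant_vector_passes_through(self):
        assert histogram_filter(np.full(20, 0.4)) == pytest.approx(0.4)

    def test_dominant_bin_mean(self):
        # bin (0.1, 0.2] holds 3 of 4 values -> mean(0.11, 0.12, 0.13)
        out = histogram_filter(np.array([0.11, 0.12, 0.13, 0.95]), 10)
        assert out == pytest.approx(0.12)

    def test_ties_break_toward_lowest_bin(self):
        assert histogram_filter(np.array([0.05, 0.95]), 10) == pytest.approx(0.05)

    def test_value_one_belongs_to_last_bin(self):
        assert histogram_filter(np.array([1.0, 1.0, 0.2]), 10) == pytest.approx(1.0)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            histogram_filter(np.array([]))


class TestMedianFilter:
    def test_constant_tensor_unchanged(self):
        t = np.full((6, 5, 4), 0.3)
        out = median_filter_tensor(t, 3, 3, 30)
        np.testing.assert_allclose(out, 0.3)

    def test_checkerboard_interior_is_neighborhood_majority(self):
        t = np.indices((8, 8)).sum(axis=0) % 2  # 0/1 checkerboard
        out = median_filter_tensor(t[:, :, None].astype(float), 3, 3, 30)
        # a 3x3 window holds 5 pixels of the center's parity -> median = center
        np.testing.assert_allclose(out[1:-1, 1:-1], t[1:-1, 1:-1])

    def test_frame_kernel_collapses_all_frames(self):
        rng = np.random.default_rng(0)
        t = rng.random((4, 4, 6))
        out = median_filter_tensor(t, 1, 1, 30)
        np.testing.assert_allclose(out, np.median(t, axis=2))

    def test_nan_entries_are_ignored(self):
        t = np.full((3, 3, 2), np.nan)
        t[1, 1, :] = 0.7
        out = median_filter_tensor(t, 3, 3, 30)
        assert out[1, 1] == pytest.approx(0.7)
        assert np.isnan(out[0, 0]) or out[0, 0] == pytest.approx(0.7)

    def test_all_nan_window_stays_nan(self):
        t = np.full((5, 5, 1), np.nan)
        out = median_filter_tensor(t, 3, 3, 1)
        assert np.isnan(out).all()


class TestAtlasConstruction:
    def test_pure_trials_give_separated_classes(self, tiny_atlas):
        assert tiny_atlas.class_separation > 0
        assert tiny_atlas.mb_rows.shape[1] == tiny_atlas.config.n_components

    def test_same_set_for_both_classes_warns_degenerate(
        self, tiny_pure_trials, tiny_cfg
    ):
        mb, _ = tiny_pure_trials
        with pytest.warns(UserWarning, match="degenerate"):
            build_atlas(mb, mb, tiny_cfg)

    def test_single_component_rows_are_scalars(self, tiny_atlas):
        assert tiny_atlas.mb_rows.shape[1] == 1
        assert tiny_atlas.hb_rows.shape[1] == 1

    def test_atlas_round_trips_through_hdf5(self, tiny_atlas, tmp_path):
        path = tmp_path / "atlas.h5"
        save_atlas(tiny_atlas, path)
        back = load_atlas(path)
        np.testing.assert_array_equal(back.mb_rows, tiny_atlas.mb_rows)
        np.testing.assert_array_equal(back.fm.basis, tiny_atlas.fm.basis)
        assert back.config == tiny_atlas.config


class TestEstimateMap:
    def test_map_values_confined_to_unit_interval_and_mask(
        self, tiny_scene, tiny_geom, tiny_atlas, tiny_cfg
    ):
        test = make_tiny_trial(tiny_scene, tiny_geom, 0.5, seed=21)
        cmap = estimate_map(test, tiny_atlas, tiny_cfg, seed=5)
        v = cmap.present_values
        assert v.size > 0
        assert v.min() >= 0.0 and v.max() <= 1.0
        mask = trial_mask(
            beamform_trial(test, tiny_cfg),
            tiny_cfg.mask_mode,
            tiny_cfg.mask_threshold,
        )
        assert np.all(mask.mask[np.isfinite(cmap.c)])

    def test_identical_seed_gives_identical_map(
        self, tiny_scene, tiny_geom, tiny_atlas, tiny_cfg
    ):
        test = make_tiny_trial(tiny_scene, tiny_geom, 0.4, seed=22)
        m1 = estimate_map(test, tiny_atlas, tiny_cfg, seed=9)
        m2 = estimate_map(test, tiny_atlas, tiny_cfg, seed=9)
        np.testing.assert_array_equal(m1.c, m2.c)

    def test_pure_mb_test_trial_estimates_high(
        self, tiny_scene, tiny_geom, tiny_atlas, tiny_cfg
    ):
        test = make_tiny_trial(tiny_scene, tiny_geom, 1.0, seed=23)
        cmap = estimate_map(test, tiny_atlas, tiny_cfg, seed=3)
        v = cmap.present_values
        assert np.mean(v >= 0.9) >= 0.9

    def test_config_mismatch_with_atlas_rejected(
        self, tiny_scene, tiny_geom, tiny_atlas, tiny_cfg
    ):
        test = make_tiny_trial(tiny_scene, tiny_geom, 0.5, seed=24)
        other = replace(tiny_cfg, dynamic_range_db=40.0)
        with pytest.raises(ValueError, match="configuration"):
            estimate_map(test, tiny_atlas, other, seed=0)


class TestSweeps:
    def test_single_setting_grid_returns_that_setting(
        self, tiny_scene, tiny_geom, tiny_cfg
    ):
        sets = [
            make_tiny_trial(tiny_scene, tiny_geom, c, seed=30 + i)
            for i, c in enumerate([0.0, 0.0, 0.5, 1.0, 1.0])
        ]
        table, best = parameter_sweep(
            sets, {"n_components": [1]}, tiny_cfg, seed=0
        )
        assert len(table) == 1
        assert best["n_components"] == 1
        assert "r_squared" in best

    def test_empty_grid_rejected(self, tiny_scene, tiny_geom, tiny_cfg):
        sets = [
            make_tiny_trial(tiny_scene, tiny_geom, c, seed=40 + i)
            for i, c in enumerate([0.0, 1.0])
        ]
        with pytest.raises(ValueError, match="grid"):
            parameter_sweep(sets, {}, tiny_cfg, seed=0)

    def test_threshold_sweep_has_one_row_per_threshold(
        self, tiny_scene, tiny_geom, tiny_cfg
    ):
        sets = [
            make_tiny_trial(tiny_scene, tiny_geom, c, seed=50 + i)
            for i, c in enumerate([0.0, 0.5, 1.0])
        ]
        thresholds = np.round(np.arange(0.3, 0.9 + 1e-9, 0.02), 2)
        table = threshold_sweep(sets, thresholds, tiny_cfg, seed=0)
        assert len(table) == 31
        assert list(table.columns) == ["threshold", "mae_percent"]
        # very high thresholds may empty the masks -> absent, not an error
        finite = table["mae_percent"].dropna()
        assert len(finite) >= 1
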