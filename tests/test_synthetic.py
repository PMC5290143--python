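"""Generators: calibration tables, spheroid scenes, cell fields."""

import numpy as np
import pandas as pd
import pytest

from beadstress.calibration import PAA_5_0225
from beadstress.errors import OutOfRangeError, PlacementError
from beadstress.synthetic import (
    SceneConfig,
    _local_stress,
    make_calibration_dataset,
    make_cell_field,
    make_spheroid_scene,
    render_disk,
)


class TestCalibrationDataset:
    def test_noiseless_linear_strains(self):
        t = make_calibration_dataset(PAA_5_0225, [0.0, 1.5, 3.0])
        assert np.allclose(t["strain"], [0.0, 0.10, 0.20], atol=1e-10)

    def test_determinism(self):
        a = make_calibration_dataset(PAA_5_0225, [0.5, 1, 2], 5, 0.01, seed=3)
        b = make_calibration_dataset(PAA_5_0225, [0.5, 1, 2], 5, 0.01, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_mean_converges(self):
        t = make_calibration_dataset(PAA_5_0225, [1.5], 10_000, 0.01, seed=1)
        assert t["strain"].mean() == pytest.approx(0.10, abs=3 * 0.01 / 100)

    def test_out_of_range_pressure(self):
        with pytest.raises(OutOfRangeError):
            make_calibration_dataset(PAA_5_0225, [100.0])


class TestStressField:
    def test_isotropic_full_transmission_strain_third(self):
        cfg = SceneConfig(
            n_spheroids=2, seed=0, stiffness_ratio=1.0, surface_transmission=1.0
        )
        scene = make_spheroid_scene(cfg, PAA_5_0225)
        assert np.allclose(scene.truth["true_strain"], 1.0 / 3.0, atol=1e-12)

    def test_surface_stress_is_screened_applied_pressure(self):
        cfg = SceneConfig()
        assert _local_stress(cfg, np.array([1.0]))[0] == pytest.approx(1.0, abs=1e-12)

    def test_power_law_value_inside(self):
        cfg = SceneConfig()
        assert _local_stress(cfg, np.array([0.3]))[0] == pytest.approx(1.294, abs=5e-4)

    def test_core_drop_tapers_stress(self):
        cfg = SceneConfig(core_drop=True)
        inner = _local_stress(cfg, np.array([0.125]))[0]
        ref = _local_stress(SceneConfig(), np.array([0.125]))[0]
        assert inner == pytest.approx(0.5 * ref, rel=1e-12)

    def test_strain_increases_with_anisotropy_at_fixed_position(self):
        # same seed => identical bead placement; stronger anisotropy (larger
        # |beta|) must not decrease the ground-truth strain anywhere inside
        base = make_spheroid_scene(SceneConfig(n_spheroids=3, seed=4), PAA_5_0225)
        strong = make_spheroid_scene(
            SceneConfig(n_spheroids=3, seed=4, stiffness_ratio=1.2), PAA_5_0225
        )
        assert np.allclose(base.truth["r_norm"], strong.truth["r_norm"])
        assert np.all(
            strong.truth["true_strain"].to_numpy()
            >= base.truth["true_strain"].to_numpy() - 1e-12
        )


class TestSpheroidScene:
    def test_determinism(self):
        cfg = SceneConfig(n_spheroids=2, seed=9)
        a = make_spheroid_scene(cfg, PAA_5_0225)
        b = make_spheroid_scene(cfg, PAA_5_0225)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for key in a.images:
            assert np.array_equal(a.images[key][0], b.images[key][0])
            assert np.array_equal(a.images[key][1], b.images[key][1])

    def test_every_truth_bead_has_an_image_pair(self, scene_small):
        keys = {(r.spheroid_id, r.bead_id) for r in scene_small.truth.itertuples()}
        assert keys == set(scene_small.images)
        assert len(scene_small.metadata) == len(scene_small.truth)

    def test_beads_inside_spheroid(self, scene_small):
        assert (scene_small.truth["r_norm"] < 1.0).all()
        lo, hi = 3, 4
        counts = scene_small.truth.groupby("spheroid_id").size()
        assert counts.between(lo, hi).all()

    def test_bead_count_and_radius_ranges(self, scene_small):
        r = scene_small.truth["true_radius_before_um"]
        assert (r >= 8.0).all() and (r < 20.0).all()
        assert (
            scene_small.truth["true_radius_after_um"]
            < scene_small.truth["true_radius_before_um"]
        ).all()

    def test_oversized_bead_fails_placement(self):
        cfg = SceneConfig(
            spheroid_radius_mean=30.0, spheroid_radius_sd=0.0,
            bead_radius_range=(16.0, 17.0),
        )
        with pytest.raises(PlacementError):
            make_spheroid_scene(cfg, PAA_5_0225)


class TestRenderDisk:
    @pytest.mark.parametrize("radius", [4.0, 8.0, 15.0])
    def test_integrated_area(self, radius):
        img = render_disk((64, 64), (32.37, 31.81), radius, 1.0, 0.0, supersample=8)
        assert img.sum() == pytest.approx(np.pi * radius**2, rel=2e-3)

    def test_background_offset(self):
        img = render_disk((32, 32), (16.0, 16.0), 5.0, 1000.0, 100.0)
        assert img.min() == pytest.approx(100.0)
        assert img.max() == pytest.approx(1000.0)


class TestCellField:
    def test_truth_aspect_ratios_and_orientation(self):
        labels, truth = make_cell_field(120.0, 150, seed=2)
        outer = truth[truth["r_norm"] > 1 / 3]
        inner = truth[truth["r_norm"] < 1 / 3]
        assert (outer["aspect_ratio"] == 2.25).all()
        assert (inner["aspect_ratio"] == 1.5).all()
        assert len(outer) > 0 and len(inner) > 0
        # tangential orientation: major axis perpendicular to the radius
        npx = labels.shape[0]
        for row in outer.head(20).itertuples():
            radial = np.arctan2(row.y_um - npx / 2.0, row.x_um - npx / 2.0)
            diff = (row.orientation - (radial + np.pi / 2) + np.pi / 2) % np.pi - np.pi / 2
            assert abs(diff) < 1e-9

    def test_determinism_and_labels(self):
        a, ta = make_cell_field(120.0, 60, seed=5)
        b, tb = make_cell_field(120.0, 60, seed=5)
        assert np.array_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)
        assert set(np.unique(a)) == set(range(61))

    def test_impossible_packing_fails(self):
        with pytest.raises(PlacementError):
            make_cell_field(60.0, 500, seed=0)
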