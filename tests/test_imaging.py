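"""IsoData thresholding, bead segmentation, strain and QC rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beadstress.errors import ConstantRegionError, NoObjectError
from beadstress.imaging import (
    QC_ELLIPTICAL,
    QC_SURFACE,
    BeadObservation,
    Rect,
    auto_roi,
    bead_radial_position,
    bead_strain_from_areas,
    isodata_threshold,
    qc_filter,
    segment_bead,
    spheroid_geometry,
)
from beadstress.synthetic import render_disk


def _obs(r_norm, ellipticity=1.0):
    return BeadObservation(
        spheroid_id="s", bead_id="b",
        area_before=100.0, area_after=90.0,
        volume_before=1.0, volume_after=0.9, strain=0.1,
        center=(0.0, 0.0, 0.0), ellipticity=ellipticity, r_norm=r_norm,
    )


class TestIsodata:
    def test_hand_iterated_two_level(self):
        # 900 px of 0 and 100 px of 200: mean 20 -> intermeans 100 -> fixed
        img = np.zeros((100, 10))
        img[:10] = 200.0
        img = img.reshape(100, 10)
        assert isodata_threshold(img) == pytest.approx(100.0, abs=0.5)

    def test_two_point_masses_midpoint(self):
        img = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)]).reshape(10, 10)
        assert isodata_threshold(img) == pytest.approx(105.0, abs=0.5)

    def test_constant_region_error(self):
        with pytest.raises(ConstantRegionError):
            isodata_threshold(np.full((20, 20), 42.0))

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_threshold_strictly_inside_intensity_range(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.normal(100, 30, (24, 24))
        img[8:16, 8:16] += rng.uniform(100, 600)
        t = isodata_threshold(img)
        assert img.min() < t < img.max()


class TestSegmentBead:
    def test_disk_area_centroid_ellipticity(self):
        img = render_disk((96, 96), (48.0, 47.0), 20.0, 200.0, 0.0)
        area, (cx, cy), ell = segment_bead(img, None, 100.0)
        assert area == pytest.approx(np.pi * 400, rel=0.02)
        assert (cx, cy) == pytest.approx((48.0, 47.0), abs=0.1)
        assert ell == pytest.approx(1.0, rel=0.02)

    def test_largest_component_wins(self):
        img = render_disk((128, 128), (40.0, 64.0), 10.0, 200.0, 0.0)
        img += render_disk((128, 128), (95.0, 64.0), 20.0, 200.0, 0.0)
        area, (cx, _), _ = segment_bead(img, None, 100.0)
        assert area == pytest.approx(np.pi * 400, rel=0.02)
        assert cx == pytest.approx(95.0, abs=0.2)

    def test_ellipse_ellipticity(self):
        yy, xx = np.mgrid[0:100, 0:100]
        mask = ((xx - 50) / 20.0) ** 2 + ((yy - 50) / 10.0) ** 2 <= 1.0
        _, _, ell = segment_bead(mask.astype(float) * 200.0, None, 100.0)
        assert ell == pytest.approx(2.0, rel=0.03)

    def test_empty_foreground(self):
        with pytest.raises(NoObjectError):
            segment_bead(np.zeros((10, 10)), None, 5.0)

    def test_area_monotone_in_threshold(self):
        img = render_disk((64, 64), (32.3, 31.8), 12.0, 200.0, 0.0)
        img = img + np.random.default_rng(0).normal(0, 5, img.shape)
        areas = [segment_bead(img, None, t)[0] for t in np.linspace(20, 180, 9)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestStrainFromAreas:
    def test_identity(self):
        _, _, s = bead_strain_from_areas(123.4, 123.4)
        assert s == 0.0

    def test_sphere_volume(self):
        v0, _, _ = bead_strain_from_areas(100 * np.pi, 100 * np.pi)
        assert v0 == pytest.approx(4188.79, rel=1e-5)

    def test_compression_ratio(self):
        _, _, s = bead_strain_from_areas(100.0, 81.0)
        assert s == pytest.approx(1 - 0.9**3, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=1e-3, max_value=1e4),
        st.floats(min_value=0.3, max_value=1.0),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, a0, ratio, k):
        _, _, s1 = bead_strain_from_areas(a0, a0 * ratio)
        _, _, s2 = bead_strain_from_areas(a0 * k, a0 * ratio * k)
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            bead_strain_from_areas(0.0, 10.0)


class TestSpheroidGeometry:
    def test_disk_radius_and_center(self):
        mask = render_disk((300, 300), (150.0, 150.0), 120.0, 1.0, 0.0) > 0.5
        geom = spheroid_geometry(mask, pixel_size=1.0, z=3.0)
        assert geom.radius == pytest.approx(120.0, rel=5e-3)
        assert geom.center == pytest.approx((150.0, 150.0, 3.0), abs=0.1)

    def test_largest_component_only(self):
        mask = render_disk((300, 300), (100.0, 150.0), 80.0, 1.0, 0.0) > 0.5
        mask |= render_disk((300, 300), (260.0, 260.0), 20.0, 1.0, 0.0) > 0.5
        geom = spheroid_geometry(mask, pixel_size=1.0)
        assert geom.radius == pytest.approx(80.0, rel=5e-3)

    def test_empty_mask(self):
        with pytest.raises(NoObjectError):
            spheroid_geometry(np.zeros((10, 10)), 1.0)


class TestRadialPositionAndQC:
    def _geom(self):
        mask = render_disk((260, 260), (130.0, 130.0), 100.0, 1.0, 0.0) > 0.5
        return spheroid_geometry(mask, pixel_size=1.0)

    def test_three_four_five(self):
        geom = self._geom()
        c = geom.center
        assert bead_radial_position((c[0] + 30, c[1] + 40, c[2]), geom) == pytest.approx(
            0.5, rel=5e-3
        )
        assert bead_radial_position(c, geom) == 0.0
        assert bead_radial_position((c[0], c[1], c[2] + geom.radius), geom) == pytest.approx(
            1.0, rel=1e-9
        )

    def test_qc_rules(self):
        geom = self._geom()
        near_surface = _obs(r_norm=(geom.radius - 5) / geom.radius)
        round_mid = _obs(r_norm=0.5, ellipticity=1.02)
        elliptical = _obs(r_norm=0.5, ellipticity=1.5)
        kept, rejected = qc_filter([near_surface, round_mid, elliptical], geom)
        assert [o.qc for o in kept] == ["pass"]
        assert sorted(o.qc for o in rejected) == [QC_ELLIPTICAL, QC_SURFACE]
        assert len(kept) + len(rejected) == 3


def test_auto_roi_frames_the_bead():
    img = render_disk((120, 120), (60.0, 58.0), 15.0, 1000.0, 100.0)
    roi = auto_roi(img)
    assert roi.x0 < 45 and roi.x1 > 75 and roi.y0 < 43 and roi.y1 > 73
    assert isinstance(roi, Rect)
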