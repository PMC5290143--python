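"""Cell shape measurement and the radial anisotropy transition."""

import numpy as np
import pandas as pd
import pytest

from beadstress.anisotropy import (
    anisotropy_profile,
    detect_transition,
    fit_ellipse_shape,
    measure_cell_field,
)
from beadstress.errors import NoObjectError
from beadstress.imaging import SpheroidGeometry
from beadstress.profile import bin_radial
from beadstress.synthetic import _rasterize_ellipse


def _geom(npx=200, radius=90.0):
    return SpheroidGeometry(
        center=(npx / 2.0, npx / 2.0, 0.0), radius=radius,
        contour_area=float(np.pi * radius**2),
    )


def _ellipse_mask(npx, center, a, b, orientation):
    mask = np.zeros((npx, npx), dtype=bool)
    rr, cc = _rasterize_ellipse((npx, npx), center, a, b, orientation)
    mask[rr, cc] = True
    return mask


class TestFitEllipseShape:
    def test_circle_aspect_ratio_near_one(self):
        mask = _ellipse_mask(200, (100.0, 100.0), 12.0, 12.0, 0.0)
        shape = fit_ellipse_shape(mask, _geom(), 1.0)
        assert shape.aspect_ratio == pytest.approx(1.0, rel=0.02)

    def test_axis_aligned_ellipse(self):
        mask = _ellipse_mask(200, (100.3, 100.7), 20.0, 10.0, 0.0)
        shape = fit_ellipse_shape(mask, _geom(), 1.0)
        assert shape.aspect_ratio == pytest.approx(2.0, rel=0.03)
        assert shape.orientation == pytest.approx(0.0, abs=0.03)
        assert shape.major == pytest.approx(40.0, rel=0.03)

    def test_tangential_cell_has_zero_alignment_angle(self):
        # cell placed along +x from the centre; tangential = vertical axis
        geom = _geom()
        mask = _ellipse_mask(200, (160.0, 100.0), 18.0, 9.0, np.pi / 2)
        shape = fit_ellipse_shape(mask, geom, 1.0)
        assert shape.alignment_angle == pytest.approx(0.0, abs=0.05)
        assert shape.r_norm == pytest.approx(60.0 / 90.0, abs=0.01)

    @pytest.mark.parametrize("angle", np.linspace(-1.4, 1.4, 8))
    def test_aspect_ratio_rotation_invariant(self, angle):
        mask = _ellipse_mask(200, (100.37, 99.81), 16.0, 8.0, angle)
        shape = fit_ellipse_shape(mask, _geom(), 1.0)
        assert shape.aspect_ratio == pytest.approx(2.0, rel=0.03)
        assert shape.orientation == pytest.approx(angle, abs=0.05)

    def test_empty_and_multicomponent_rejected(self):
        with pytest.raises(NoObjectError):
            fit_ellipse_shape(np.zeros((20, 20), bool), _geom(), 1.0)
        two = np.zeros((40, 40), bool)
        two[5:10, 5:10] = True
        two[25:30, 25:30] = True
        with pytest.raises(ValueError):
            fit_ellipse_shape(two, _geom(), 1.0)


class TestAnisotropyProfile:
    def test_step_field_bin_means(self, cell_field):
        labels, truth, geom = cell_field
        shapes = measure_cell_field(labels, geom, 1.0)
        assert len(shapes) == len(truth)
        prof = anisotropy_profile(shapes, n_bins=9)
        outer = prof.bins[prof.bins["r_norm"] > 0.45]["value"]
        inner = prof.bins["value"].iloc[0]
        assert ((outer >= 2.0) & (outer <= 2.5)).all()
        assert inner == pytest.approx(1.5, abs=0.15)

    def test_all_circles_profile_flat(self):
        from beadstress.anisotropy import CellShape

        rng = np.random.default_rng(0)
        shapes = [
            CellShape((0, 0), 10, 10, 1.0, 0.0, 0.0, r) for r in rng.uniform(0.05, 0.95, 40)
        ]
        prof = anisotropy_profile(shapes, n_bins=5)
        assert np.allclose(prof.bins["value"], 1.0)


def _step_profile(split, n_bins=9, lo=1.5, hi=2.25):
    centers = (np.arange(n_bins) + 0.5) / n_bins
    vals = np.where(centers < split, lo, hi)
    return bin_radial(
        pd.DataFrame({"r_norm": centers, "value": vals}), "fixed_width", n_bins
    )


class TestDetectTransition:
    @pytest.mark.parametrize("split", [1.0 / 3.0, 0.5])
    def test_step_profile_change_point(self, split):
        prof = _step_profile(split)
        res = detect_transition(prof)
        assert res.r_transition == pytest.approx(split, abs=1.0 / 9.0)

    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(1.5, 0.05, 4), rng.normal(2.2, 0.05, 5)])
        centers = (np.arange(9) + 0.5) / 9
        prof = bin_radial(
            pd.DataFrame({"r_norm": centers, "value": v}), "fixed_width", 9
        )
        # brute-force oracle: try every split, keep the lowest total SSE
        best, best_k = np.inf, None
        for k in range(1, 9):
            sse = sum(np.sum((seg - seg.mean()) ** 2) for seg in (v[:k], v[k:]))
            if sse < best:
                best, best_k = sse, k
        res = detect_transition(prof)
        assert res.split_index == best_k

    def test_flat_profile_reports_no_transition(self):
        prof = _step_profile(0.5, lo=2.0, hi=2.0)
        res = detect_transition(prof)
        assert res.r_transition is None

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            detect_transition(_step_profile(0.5, n_bins=3))


def test_detected_transition_near_third_on_generated_field(cell_field):
    labels, _, geom = cell_field
    shapes = measure_cell_field(labels, geom, 1.0)
    prof = anisotropy_profile(shapes, n_bins=9)
    res = detect_transition(prof)
    bin_width = float(np.diff(prof.bins["r_norm"]).mean())
    assert res.r_transition == pytest.approx(1.0 / 3.0, abs=bin_width)
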