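"""ROI grid construction, region assignment, intensities and line profiles."""

import numpy as np
import pytest

import axonquant as aq
from axonquant.grid import (
    EXCLUDED,
    RoiWindow,
    assign_regions,
    build_grid,
    label_map_from_polygons,
    line_profile,
    roi_mean_intensity,
)


class TestBuildGrid:
    def test_counting_contract(self):
        g = build_grid((400.0, 500.0), spacing_um=100, window_um=89.51)
        assert len(g.included) == 4 * 5

    def test_extent_smaller_than_window_has_no_included_windows(self):
        g = build_grid((50.0, 50.0), spacing_um=100, window_um=89.51)
        assert len(g.included) == 0
        assert all(w.region == EXCLUDED for w in g.windows)

    def test_origin_shift_by_one_spacing_matches_enumeration_oracle(self):
        extent, spacing, window = (430.0, 430.0), 100.0, 89.51
        base = build_grid(extent, spacing, window, origin_um=(0.0, 0.0))
        shifted = build_grid(extent, spacing, window, origin_um=(100.0, 0.0))
        # oracle: brute-force enumeration of fully contained corner positions
        def contained(origin0):
            out = set()
            k = 0
            while origin0 + k * spacing < extent[0]:
                y = origin0 + k * spacing
                m = 0
                while m * spacing < extent[1]:
                    x = m * spacing
                    if y >= 0 and y + window <= extent[0] and x + window <= extent[1]:
                        out.add((y, x))
                    m += 1
                k += 1
            return out
        assert {w.origin_um for w in base.included} == contained(0.0)
        assert {w.origin_um for w in shifted.included} == contained(100.0)
        # the shifted set is the base set minus the first row
        assert {w.origin_um for w in shifted.included} == {
            o for o in contained(0.0) if o[0] >= 100.0
        }

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_grid((100.0, 100.0), spacing_um=0)
        with pytest.raises(ValueError):
            build_grid((100.0, 100.0), window_um=-1)


class TestAssignRegions:
    def _grid_one_window(self):
        return build_grid((10.0, 10.0), spacing_um=10, window_um=10, pixel_size_um=1.0)

    def test_majority_rule(self):
        g = self._grid_one_window()
        labels = np.full((10, 10), "core", dtype="<U10")
        labels[:, :4] = "transition"  # 60/40 split
        assign_regions(g, labels)
        assert g.windows[0].region == "core"

    def test_pure_window(self):
        g = self._grid_one_window()
        assign_regions(g, np.full((10, 10), "MDm", dtype="<U10"))
        assert g.windows[0].region == "MDm"

    def test_exact_tie_excluded(self):
        g = self._grid_one_window()
        labels = np.full((10, 10), "core", dtype="<U10")
        labels[:, :5] = "transition"  # exact 50/50
        assign_regions(g, labels)
        assert not g.windows[0].included and g.windows[0].region == EXCLUDED

    def test_majority_none_excluded(self):
        g = self._grid_one_window()
        labels = np.full((10, 10), "none", dtype="<U10")
        labels[:, :2] = "core"
        assign_regions(g, labels)
        assert not g.windows[0].included

    def test_missing_label_map_errors(self):
        with pytest.raises(ValueError):
            assign_regions(self._grid_one_window(), None)


class TestRoiMeanIntensity:
    def test_constant_image(self):
        w = RoiWindow((0.0, 0.0), 5.0)
        assert roi_mean_intensity(np.full((10, 10), 7.5), w) == 7.5

    def test_noiseless_region_field_exact(self):
        levels = {"MDm": 10.0, "transition": 20.0, "core": 40.0}
        image, labels = aq.generate_region_field((300, 300), levels, noise_sd=0.0)
        g = build_grid((300.0, 300.0))
        assign_regions(g, labels)
        aq.measure_grid(g, {"CR": image})
        for w in g.included:
            assert w.measurements["mean_CR"] == levels[w.region]

    def test_noisy_field_within_three_sem(self):
        levels = {"MDm": 10.0, "transition": 20.0, "core": 40.0}
        sd = 1.0
        image, labels = aq.generate_region_field((300, 300), levels, noise_sd=sd, seed=5)
        g = build_grid((300.0, 300.0))
        assign_regions(g, labels)
        for w in g.included:
            n = int(round(w.side_um)) ** 2
            mean = roi_mean_intensity(image, w)
            assert abs(mean - levels[w.region]) < 3 * sd / np.sqrt(n)

    def test_excluded_window_errors(self):
        w = RoiWindow((0.0, 0.0), 5.0, region=EXCLUDED, included=False)
        with pytest.raises(ValueError):
            roi_mean_intensity(np.ones((10, 10)), w)

    def test_region_intensity_ordering_recovered(self):
        """The core > transition > MDm gradient survives sampling noise."""
        image, labels = aq.generate_region_field((300, 300), noise_sd=2.0, seed=9)
        g = build_grid((300.0, 300.0))
        assign_regions(g, labels)
        aq.measure_grid(g, {"CR": image})
        means = {}
        for w in g.included:
            means.setdefault(w.region, []).append(w.measurements["mean_CR"])
        assert np.mean(means["core"]) > np.mean(means["transition"]) > np.mean(means["MDm"])

    def test_translation_covariance(self):
        """Shifting image and grid origin together leaves measurements unchanged."""
        rng = np.random.default_rng(4)
        image = rng.random((220, 220)) * 100
        g0 = build_grid((200.0, 200.0), spacing_um=100, window_um=89.51)
        vals0 = [roi_mean_intensity(image[:200, :200], w) for w in g0.included]
        shifted = np.zeros((220, 220))
        shifted[20:, 20:] = image[:200, :200]
        g1 = build_grid((220.0, 220.0), spacing_um=100, window_um=89.51,
                        origin_um=(20.0, 20.0))
        vals1 = [roi_mean_intensity(shifted, w) for w in g1.included]
        assert vals1 == pytest.approx(vals0)


class TestLineProfile:
    def test_constant_image_gives_flat_profile(self):
        prof = line_profile(np.full((40, 40), 3.0), [(20.0, 5.0), (20.0, 35.0)],
                            band_width_um=4.0, step_um=1.0)
        assert np.allclose(prof.intensity, 3.0)
        assert np.all(np.diff(prof.distance_um) > 0)

    def test_step_edge_profile_is_monotone_sigmoid(self):
        image = np.zeros((40, 80))
        image[:, 40:] = 10.0
        prof = line_profile(image, [(20.0, 10.0), (20.0, 70.0)],
                            band_width_um=4.0, step_um=1.0)
        assert prof.intensity[0] == pytest.approx(0.0, abs=1e-9)
        assert prof.intensity[-1] == pytest.approx(10.0, abs=1e-9)
        assert np.all(np.diff(prof.intensity) >= -1e-9)

    def test_single_pixel_band_equals_nearest_line_sampling(self):
        rng = np.random.default_rng(1)
        image = rng.random((30, 60))
        poly = [(15.0, 5.0), (15.0, 55.0)]
        prof = line_profile(image, poly, band_width_um=1.0, step_um=1.0)
        from scipy import ndimage
        d = prof.distance_um
        coords = np.vstack([np.full_like(d, 15.0), 5.0 + d])
        expected = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
        assert prof.intensity == pytest.approx(expected)

    def test_zero_length_polyline_errors(self):
        with pytest.raises(ValueError):
            line_profile(np.ones((10, 10)), [(5.0, 5.0), (5.0, 5.0)], 2.0, 1.0)


class TestPolygonLabels:
    def test_rectangles_rasterize_to_expected_labels(self):
        polygons = {
            "core": [(0.0, 0.0), (0.0, 10.0), (20.0, 10.0), (20.0, 0.0)],
            "MDm": [(0.0, 10.0), (0.0, 20.0), (20.0, 20.0), (20.0, 10.0)],
        }
        labels = label_map_from_polygons(polygons, (20, 20), pixel_size_um=1.0)
        assert np.all(labels[:, :10] == "core")
        assert np.all(labels[:, 10:] == "MDm")
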