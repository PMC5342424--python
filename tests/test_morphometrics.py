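"""Morphometric features: analytic shapes, oracles, and invariances."""

import numpy as np
import pytest

import radiogen_psp as r
from radiogen_psp.morphometrics import slice_feature_table


def disk_mask(radius, shape=(64, 64), label=1):
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    m = np.zeros(shape, np.uint8)
    m[(rr - h / 2) ** 2 + (cc - w / 2) ** 2 <= radius**2] = label
    return m


class TestSliceFeatures:
    def test_disk_area_and_counts(self):
        sf = r.slice_features(disk_mask(10))
        assert abs(sf.enhanced.area - np.pi * 100) < 0.02 * np.pi * 100
        assert sf.enhanced.region_count == 1
        assert sf.necrotic.area == 0
        assert sf.necrotic.region_count == 0
        assert sf.enhanced.area_proportion == 1.0

    def test_two_disjoint_squares(self):
        m = np.zeros((40, 40), np.uint8)
        m[2:7, 2:7] = 1
        m[20:25, 20:25] = 1
        sf = r.slice_features(m)
        assert sf.enhanced.region_count == 2
        assert sf.enhanced.area == 50
        assert sf.enhanced.area_proportion == 1.0

    def test_ring_margin_thickness_near_band_width(self):
        stack = r.generate_mask_stack(r.ShapeSpec(shape="ring", outer=10, inner=6))
        sf = r.slice_features(stack.slices[0])
        assert abs(sf.enhanced.thickness - 4.0) < 0.15 * 4.0

    def test_thickness_matches_brute_force_distance_transform(self):
        # independent oracle: per-pixel minimum distance to any
        # complement pixel by explicit pairwise search
        stack = r.generate_mask_stack(
            r.ShapeSpec(shape="ring", outer=8, inner=4), image_shape=(24, 24)
        )
        mask = stack.slices[0] == 1
        inside = np.argwhere(mask).astype(float)
        outside = np.argwhere(~mask).astype(float)
        dists = np.sqrt(((inside[:, None, :] - outside[None, :, :]) ** 2).sum(-1)).min(1)
        expected = 4.0 * (dists - 0.5).mean()
        sf = r.slice_features(stack.slices[0])
        np.testing.assert_allclose(sf.enhanced.thickness, expected, rtol=1e-12)

    def test_uniform_band_thickness_equals_width(self):
        m = np.zeros((30, 60), np.uint8)
        m[10:16, :] = 1  # infinite band approximation, width 6
        sf = r.slice_features(m)
        assert abs(sf.enhanced.thickness - 6.0) < 0.2

    def test_equivalent_radius_definition(self):
        sf = r.slice_features(disk_mask(10))
        np.testing.assert_allclose(
            sf.enhanced.equivalent_radius, np.sqrt(sf.enhanced.area / np.pi)
        )

    def test_area_proportions_sum_to_one(self):
        stack = r.generate_mask_stack(r.ShapeSpec(shape="ring", outer=12, inner=5))
        sf = r.slice_features(stack.slices[0])
        assert sf.enhanced.area_proportion + sf.necrotic.area_proportion == pytest.approx(1.0)

    def test_pixel_size_scales_area_to_mm2(self):
        sf = r.slice_features(disk_mask(5), pixel_size=0.5)
        np.testing.assert_allclose(sf.enhanced.area_mm2, sf.enhanced.area * 0.25)


class TestPrimaryRegionProps:
    def test_disk_is_round(self):
        pp = r.primary_region_props(disk_mask(20), 1)
        assert pp.eccentricity < 0.05
        assert abs(pp.compactness - 1.0) < 0.10
        assert abs(pp.sphericity - 1.0) < 0.05

    def test_axis_aligned_rectangle(self):
        m = np.zeros((40, 40), np.uint8)
        m[10:20, 5:25] = 1  # 10 rows x 20 cols
        pp = r.primary_region_props(m, 1)
        assert pp.bbox_area == 200
        assert abs(pp.solidity - 1.0) < 0.02
        assert abs(pp.orientation) < 0.05  # elongated along the horizontal axis

    def test_ellipse_axes_against_pixel_moment_oracle(self):
        stack = r.generate_mask_stack(
            r.ShapeSpec(shape="ellipse", axes=(10, 20)), image_shape=(64, 64)
        )
        mask = stack.slices[0] == 1
        pp = r.primary_region_props(stack.slices[0], 1)
        assert abs(pp.major_axis_length / pp.minor_axis_length - 2.0) < 0.05 * 2.0
        assert abs(pp.eccentricity - np.sqrt(3) / 2) < 0.05 * np.sqrt(3) / 2
        # oracle: exhaustive second-order moments from raw pixel coordinates
        coords = np.argwhere(mask).astype(float)
        centered = coords - coords.mean(axis=0)
        cov = centered.T @ centered / len(coords)
        lams = np.sort(np.linalg.eigvalsh(cov))
        np.testing.assert_allclose(pp.major_axis_length, 4 * np.sqrt(lams[1]), rtol=1e-6)
        np.testing.assert_allclose(pp.minor_axis_length, 4 * np.sqrt(lams[0]), rtol=1e-6)

    def test_largest_component_is_selected(self):
        m = np.zeros((30, 30), np.uint8)
        m[2:5, 2:5] = 1  # area 9
        m[10:20, 10:20] = 1  # area 100, the primary region
        pp = r.primary_region_props(m, 1)
        assert pp.area == 100

    def test_empty_class_raises(self):
        with pytest.raises(r.EmptyRegionError, match="necrotic"):
            r.primary_region_props(disk_mask(5), 2)


class TestInvariances:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rotation_by_90_degrees(self, k):
        stack = r.generate_mask_stack(
            r.ShapeSpec(shape="ellipse", axes=(8, 16), inner=3), image_shape=(48, 48)
        )
        m = stack.slices[0]
        rot = np.rot90(m, k)
        a, b = r.primary_region_props(m, 1), r.primary_region_props(rot, 1)
        assert a.area == b.area
        np.testing.assert_allclose(a.solidity, b.solidity)
        np.testing.assert_allclose(a.eccentricity, b.eccentricity)
        assert abs(a.perimeter - b.perimeter) < 0.05 * a.perimeter
        assert abs(a.compactness - b.compactness) < 0.05 * a.compactness
        fa, fb = r.slice_features(m), r.slice_features(rot)
        assert fa.enhanced.region_count == fb.enhanced.region_count
        assert fa.enhanced.area == fb.enhanced.area

    def test_doubling_linear_size(self):
        small = r.primary_region_props(disk_mask(10), 1)
        big = r.primary_region_props(disk_mask(20), 1)
        assert abs(big.area / small.area - 4.0) < 0.05 * 4.0
        assert abs(big.perimeter / small.perimeter - 2.0) < 0.05 * 2.0
        assert abs(big.sphericity - small.sphericity) < 0.05
        assert abs(big.eccentricity - small.eccentricity) < 0.05


class TestAggregation:
    def test_single_slice_case_collapses(self):
        table = slice_feature_table(disk_mask(8))
        vec = r.aggregate_case([table])
        for name, value in table.items():
            assert vec[f"mean_{name}"] == value
            assert vec[f"max_{name}"] == value
            assert vec[f"min_{name}"] == value
            assert vec[f"sum_{name}"] == value
            assert vec[f"largest_{name}"] == value

    def test_three_slice_aggregates(self):
        masks = []
        for rows in (2, 4, 6):  # enhanced areas 10, 20, 30
            m = np.zeros((20, 20), np.uint8)
            m[5 : 5 + rows, 5:10] = 1
            masks.append(m)
        vec = r.case_features(masks)
        assert vec["largest_enhanced_area"] == 30
        assert vec["mean_enhanced_area"] == 20
        assert vec["max_enhanced_area"] == 30
        assert vec["min_enhanced_area"] == 10
        assert vec["sum_enhanced_area"] == 60

    def test_random_stack_matches_independent_reaggregation(self, rng):
        stacks = []
        for _ in range(5):
            m = (rng.random((32, 32)) < 0.2).astype(np.uint8)
            m[rng.random((32, 32)) < 0.05] = 2
            stacks.append(m)
        tables = [slice_feature_table(m) for m in stacks]
        vec = r.aggregate_case(tables)
        # oracle: recompute every aggregate feature-by-feature
        areas = [t["enhanced_area"] + t["necrotic_area"] for t in tables]
        largest = int(np.argmax(areas))
        for name in tables[0].index:
            column = np.array([t[name] for t in tables])
            assert vec[f"largest_{name}"] == tables[largest][name]
            np.testing.assert_allclose(vec[f"mean_{name}"], column.mean())
            np.testing.assert_allclose(vec[f"max_{name}"], column.max())
            np.testing.assert_allclose(vec[f"min_{name}"], column.min())
            np.testing.assert_allclose(vec[f"sum_{name}"], column.sum())

    def test_manifest_covers_exactly_the_vector(self):
        vec = r.case_features([disk_mask(6)])
        manifest = r.feature_manifest()
        assert set(manifest) == set(vec.index)
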