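"""Background estimation, almost-max projection, masking, and object
identification within one field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import two_channel_config
from hcfm.config import AcquisitionConfig
from hcfm.detect import (
    almost_max_project,
    estimate_background,
    identify_objects,
    make_channel_mask,
    make_vignette,
    extract_objects,
    median_filter_2d,
)
from hcfm.io import FieldOfView, Projection, VoxelGrid


def _field_from_array(arr, config, bf_value=600):
    bf = np.full(arr.shape, bf_value, dtype=arr.dtype)
    return FieldOfView(
        {"bright_field": VoxelGrid(bf, config), "dna": VoxelGrid(arr, config)},
        0, 0, "t", config,
    )


def sorted_second_highest(values):
    """Independent oracle: descending sort of each Z-column, take index 1."""
    out = np.empty(values.shape[:2], dtype=values.dtype)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            out[i, j] = np.sort(values[i, j, :])[::-1][1]
    return out


class TestBackground:
    def test_all_zero_channel_hits_floor(self):
        config = two_channel_config(frame_pixels=8, z_planes=2)
        arr = np.zeros((8, 8, 2), dtype=np.uint16)
        bg = estimate_background([_field_from_array(arr, config)], config)
        assert bg.mean["dna"] == 0 and bg.std["dna"] == 0
        assert bg.threshold["dna"] == 1.0

    def test_known_voxel_population(self):
        # voxels {0,0,0,0,10,10,10,10}: mean 5, population std 5 -> 12.5
        config = two_channel_config(frame_pixels=2, z_planes=2)
        arr = np.array([0, 0, 0, 0, 10, 10, 10, 10], dtype=np.uint16).reshape(2, 2, 2)
        bg = estimate_background([_field_from_array(arr, config)], config)
        assert bg.mean["dna"] == pytest.approx(5.0)
        assert bg.std["dna"] == pytest.approx(5.0)
        assert bg.threshold["dna"] == pytest.approx(12.5)

    def test_large_sample_gaussian(self):
        # Monte-Carlo: N(100, 10) at n >= 1e6 -> threshold in [114, 116]
        config = two_channel_config(frame_pixels=128, z_planes=64)
        rng = np.random.default_rng(5)
        arr = np.clip(rng.normal(100, 10, size=(128, 128, 64)), 0, None).astype(np.uint16)
        bg = estimate_background([_field_from_array(arr, config)], config)
        assert 114 <= bg.threshold["dna"] <= 116

    def test_statistics_pool_across_fields(self):
        config = two_channel_config(frame_pixels=2, z_planes=2)
        a = np.zeros((2, 2, 2), dtype=np.uint16)
        b = np.full((2, 2, 2), 10, dtype=np.uint16)
        bg = estimate_background(
            [_field_from_array(a, config), _field_from_array(b, config)], config
        )
        assert bg.mean["dna"] == pytest.approx(5.0)
        assert bg.std["dna"] == pytest.approx(5.0)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            estimate_background([], two_channel_config())

    def test_brightfield_has_no_threshold(self):
        config = two_channel_config(frame_pixels=4, z_planes=2)
        arr = np.ones((4, 4, 2), dtype=np.uint16)
        bg = estimate_background([_field_from_array(arr, config)], config)
        assert "bright_field" not in bg.threshold

    def test_threshold_shift_equivariance(self):
        # raising every voxel by k raises the threshold by exactly k
        config = two_channel_config(frame_pixels=8, z_planes=4)
        rng = np.random.default_rng(6)
        arr = rng.integers(50, 150, size=(8, 8, 4)).astype(np.uint16)
        k = 37
        bg0 = estimate_background([_field_from_array(arr, config)], config)
        bg1 = estimate_background([_field_from_array(arr + k, config)], config)
        assert bg1.threshold["dna"] == pytest.approx(bg0.threshold["dna"] + k)


class TestAlmostMax:
    @pytest.mark.parametrize(
        "column,expected",
        [([2, 7, 100], 7), ([5, 5, 5], 5), ([9, 9, 1], 9)],
    )
    def test_column_cases(self, column, expected):
        arr = np.array(column, dtype=np.uint16).reshape(1, 1, -1)
        assert almost_max_project(arr).values[0, 0] == expected

    def test_matches_sort_oracle_on_random_stacks(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            stack = rng.integers(0, 1000, size=(8, 8, 5)).astype(np.uint16)
            np.testing.assert_array_equal(
                almost_max_project(stack).values, sorted_second_highest(stack)
            )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(1, 7), rng.integers(1, 7), rng.integers(2, 8))
        stack = rng.integers(0, 65535, size=shape).astype(np.uint16)
        np.testing.assert_array_equal(
            almost_max_project(stack).values, sorted_second_highest(stack)
        )

    def test_single_plane_rejected(self):
        with pytest.raises(ValueError):
            almost_max_project(np.zeros((4, 4, 1), dtype=np.uint16))


class TestChannelMask:
    def test_uniform_below_threshold_is_empty(self):
        proj = Projection(np.full((16, 16), 10.0), "dna")
        assert not make_channel_mask(proj, 50.0).any()

    def test_single_bright_pixel_removed_by_median(self):
        img = np.zeros((16, 16))
        img[8, 8] = 1000.0
        assert not make_channel_mask(Projection(img, "dna"), 50.0).any()

    def test_bright_square_matches_brute_force_median(self):
        img = np.zeros((16, 16))
        img[5:10, 5:10] = 100.0
        mask = make_channel_mask(Projection(img, "dna"), 50.0)
        # brute-force 3x3 median with reflected edges
        padded = np.pad(img, 1, mode="reflect")
        expected = np.empty_like(img)
        for i in range(16):
            for j in range(16):
                expected[i, j] = np.median(padded[i:i + 3, j:j + 3])
        np.testing.assert_array_equal(mask, expected > 50.0)


def _disk_field(config, disks, value=200):
    """Disks given as (cx, cy, diameter) in µm over a zero background."""
    n, z = config.frame_pixels, config.z_planes
    arr = np.zeros((n, n, z), dtype=np.uint16)
    xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    for cx, cy, d in disks:
        r_px = (d / 2) / config.voxel_size_xy_um
        inside = (xx - cx / config.voxel_size_xy_um) ** 2 + (
            yy - cy / config.voxel_size_xy_um
        ) ** 2 <= r_px**2
        arr[inside, :] = value
    return _field_from_array(arr, config)


class TestIdentifyObjects:
    def test_size_and_border_filters_on_disks(self):
        # 3 µm disk (~7.1 µm² < 12.6) removed; 6 and 10 µm disks kept;
        # a 10 µm disk touching the left border removed
        config = two_channel_config(frame_pixels=256, z_planes=3)
        fov = _disk_field(
            config,
            [(12, 12, 3.0), (30, 12, 6.0), (12, 34, 10.0), (3, 24, 10.0)],
        )
        masks = identify_objects(fov, {"dna": 50.0}, config)
        areas = sorted(m.area_um2 for m in masks)
        assert len(masks) == 2
        assert areas[0] == pytest.approx(np.pi * 3**2, rel=0.1)
        assert areas[1] == pytest.approx(np.pi * 5**2, rel=0.1)

    def test_empty_field_gives_no_objects(self):
        config = two_channel_config(frame_pixels=32, z_planes=3)
        fov = _field_from_array(np.zeros((32, 32, 3), dtype=np.uint16), config)
        assert identify_objects(fov, {"dna": 50.0}, config) == []

    def test_overlapping_channel_masks_merge(self):
        # DNA and chlorophyll masks of one cell overlap -> a single object
        from hcfm.config import ChannelRole

        config = AcquisitionConfig(
            frame_pixels=128, field_width_um=128 * 0.188, z_planes=3,
            channels=(
                ChannelRole("bright_field", "bright_field", False),
                ChannelRole("dna", "dna", True),
                ChannelRole("chlorophyll", "chlorophyll", True),
            ),
        )
        n = 128
        dna = np.zeros((n, n, 3), dtype=np.uint16)
        chl = np.zeros((n, n, 3), dtype=np.uint16)
        dna[40:70, 40:70, :] = 200
        chl[55:85, 55:85, :] = 200
        fov = FieldOfView(
            {
                "bright_field": VoxelGrid(np.full((n, n, 3), 600, np.uint16), config),
                "dna": VoxelGrid(dna, config),
                "chlorophyll": VoxelGrid(chl, config),
            },
            0, 0, "t", config,
        )
        masks = identify_objects(fov, {"dna": 50.0, "chlorophyll": 50.0}, config)
        assert len(masks) == 1

    @pytest.mark.parametrize(
        "shape,kept",
        [((19, 19), True), ((18, 20), False)],
        ids=["357px-retained", "356px-removed"],
    )
    def test_area_filter_boundary(self, shape, kept):
        # a k x k rectangle loses its 4 corners to the 3x3 median filter:
        # 19x19 -> 357 px = 12.6178 µm² (kept); 18x20 -> 356 px = 12.5825 (removed)
        config = two_channel_config(frame_pixels=128, z_planes=3)
        a, b = shape
        arr = np.zeros((128, 128, 3), dtype=np.uint16)
        arr[30:30 + a, 30:30 + b, :] = 200
        fov = _field_from_array(arr, config)
        masks = identify_objects(fov, {"dna": 50.0}, config)
        if kept:
            assert len(masks) == 1 and len(masks[0].pixels) == 357
        else:
            assert masks == []

    def test_bit_depth_equivalence_after_threshold_scaling(self):
        # identical content at 8-bit and 16-bit (x257) -> identical masks
        config = two_channel_config(frame_pixels=128, z_planes=3)
        rng = np.random.default_rng(7)
        base = rng.integers(0, 40, size=(128, 128, 3)).astype(np.uint8)
        base[40:80, 40:80, :] = 150
        f8 = _field_from_array(base, config, bf_value=200)
        f16 = _field_from_array((base.astype(np.uint16)) * 257, config)
        m8 = identify_objects(f8, {"dna": 90.0}, config)
        m16 = identify_objects(f16, {"dna": 90.0 * 257}, config)
        assert len(m8) == len(m16) == 1
        np.testing.assert_array_equal(m8[0].pixels, m16[0].pixels)


class TestVignette:
    def _object(self):
        config = two_channel_config(frame_pixels=64, z_planes=4)
        arr = np.zeros((64, 64, 4), dtype=np.uint16)
        arr[20:45, 20:45, :] = 120
        arr[30, 30, 2] = 5000  # single-voxel spike
        fov = _field_from_array(arr, config)
        masks = identify_objects(fov, {"dna": 50.0}, config)
        return extract_objects(fov, masks)[0]

    def test_shape_matches_bounding_box(self):
        obj = self._object()
        vig = make_vignette(obj)
        x0, y0, x1, y1 = obj.bbox
        assert all(v.shape == (x1 - x0, y1 - y0) for v in vig.values())

    def test_spike_absent_from_vignette(self):
        from hcfm.detect import object_projections

        obj = self._object()
        # the 5000-intensity single-voxel spike is suppressed by the
        # almost-max projection: the raw projection tops out at the body
        # intensity, and the stretched vignette is flat (constant body)
        proj = object_projections(obj)["dna"]
        assert proj.max() == 120
        vig = make_vignette(obj)["dna"]
        assert vig.min() >= 0.0 and vig.max() <= 1.0
        assert np.ptp(vig) == 0.0

    def test_constant_object_gives_flat_vignette(self):
        config = two_channel_config(frame_pixels=64, z_planes=4)
        arr = np.zeros((64, 64, 4), dtype=np.uint16)
        arr[20:45, 20:45, :] = 120
        fov = _field_from_array(arr, config)
        obj = extract_objects(fov, identify_objects(fov, {"dna": 50.0}, config))[0]
        vig = make_vignette(obj)["bright_field"]  # constant channel
        assert np.ptp(vig) == 0.0
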