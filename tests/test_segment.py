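import numpy as np
import pytest
from skimage.draw import disk

from condenstat import (
    CellROI,
    ConfigurationError,
    SimParams,
    auto_background_region,
    compute_threshold,
    estimate_background,
    measure_objects,
    segment_2d,
    segment_3d,
    select_reference_frame,
    simulate_cell,
)
from condenstat.datamodel import ImageStack


def frame_stack(per_frame_values, yx=6):
    """Stack whose frames are constant at the given values."""
    t = len(per_frame_values)
    data = np.zeros((t, 1, 1, yx, yx))
    for i, v in enumerate(per_frame_values):
        data[i, 0, 0] = v
    return ImageStack(data=data, pixel_size_um=0.1, channel_names=["c"])


full = CellROI("cell", np.ones((6, 6), bool))


class TestReferenceFrame:
    @pytest.mark.parametrize(
        "means, expected",
        [([10, 20, 15], 1), ([5], 0), ([7, 7], 0)],
        ids=["max", "single", "tie-earliest"],
    )
    def test_picks_brightest_frame(self, means, expected):
        assert select_reference_frame(frame_stack(means), full, "c") == expected


class TestBackground:
    def test_constant_region(self):
        frame = np.full((6, 6), 100.0)
        assert estimate_background(frame, full) == (100.0, 0.0)

    def test_sample_sd_uses_n_minus_one(self):
        frame = np.zeros((1, 2))
        frame[0] = [90.0, 110.0]
        mean, sd = estimate_background(frame, np.ones((1, 2), bool))
        assert mean == 100.0
        assert sd == pytest.approx(np.sqrt(200.0))  # 14.1421...

    def test_single_pixel_region_rejected(self):
        mask = np.zeros((6, 6), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError, match="SD undefined"):
            estimate_background(np.zeros((6, 6)), mask)

    def test_auto_region_recovers_background_stats(self):
        p = SimParams(seed=8, bg_mean=200.0, bg_sd=20.0)
        stack, roi, _ = simulate_cell(p)
        frame = stack.frame(0, "polyQ")
        region = auto_background_region(frame, roi, stack.pixel_size_um)
        mean, sd = estimate_background(frame, region)
        assert mean == pytest.approx(200.0, rel=0.01)
        assert sd == pytest.approx(20.0, rel=0.10)


class TestThreshold:
    @pytest.mark.parametrize(
        "mean, sd, k, expected",
        [(100, 10, 2.5, 125.0), (100, 0, 2.5, 100.0), (0, 1, 0, 0.0)],
    )
    def test_mean_plus_k_sd(self, mean, sd, k, expected):
        assert compute_threshold(mean, sd, k) == expected


class TestSegment2D:
    def test_all_background_yields_no_objects(self):
        out = segment_2d(np.zeros((16, 16)), None, 0.5, 16)
        assert out.n_objects == 0

    def test_size_filter_keeps_only_the_large_square(self):
        img = np.zeros((32, 32))
        img[2:7, 2:7] = 10.0   # 25 px
        img[20:23, 20:23] = 10.0  # 9 px
        out = segment_2d(img, None, 5.0, 16)
        assert out.n_objects == 1
        assert out.records.n_px.tolist() == [25]

    def test_threshold_is_strict_inequality(self):
        img = np.full((8, 8), 5.0)
        assert segment_2d(img, None, 5.0, 1).n_objects == 0

    def test_roi_restricts_detection(self):
        img = np.full((8, 8), 10.0)
        roi = np.zeros((8, 8), bool)
        roi[:4, :4] = True
        out = segment_2d(img, roi, 5.0, 1)
        assert out.records.n_px.tolist() == [16]

    def test_filter_monotonicity(self, cycling_cell):
        """Raising the threshold or minimum size never increases counts."""
        stack, roi, _ = cycling_cell
        frame = stack.frame(0, "polyQ")
        counts_thr = [segment_2d(frame, roi, thr, 16).n_objects
                      for thr in (230, 250, 280, 350)]
        assert counts_thr == sorted(counts_thr, reverse=True)
        counts_min = [segment_2d(frame, roi, 250, m).n_objects
                      for m in (1, 16, 64, 256)]
        assert counts_min == sorted(counts_min, reverse=True)


class TestSegment3D:
    def make_cube(self):
        vol = np.zeros((6, 10, 10))
        vol[1:5, 1:5, 1:5] = 10.0
        return vol

    def test_cube_at_exact_voxel_filter_boundary(self):
        out = segment_3d(self.make_cube(), None, 5.0, 64)
        assert out.n_objects == 1
        assert out.records.n_vox.tolist() == [64]
        assert segment_3d(self.make_cube(), None, 5.0, 65).n_objects == 0

    def test_empty_volume(self):
        assert segment_3d(np.zeros((4, 8, 8)), None, 1.0, 64).n_objects == 0

    def test_single_section_directed_to_2d(self):
        with pytest.raises(ValueError, match="segment_2d"):
            segment_3d(np.zeros((1, 8, 8)), None, 1.0, 64)


class TestMeasureObjects:
    def test_area_from_pixel_count_at_default_pixel_size(self):
        img = np.zeros((16, 16))
        img[4:8, 4:8] = 10.0  # 16 px
        out = segment_2d(img, None, 5.0, 16)
        rec = measure_objects(out, 0.0851)
        assert rec.n_px[0] == 16
        assert rec.area_um2[0] == pytest.approx(16 * 0.0851**2)
        assert rec.area_um2[0] == pytest.approx(0.116, rel=0.003)

    @pytest.mark.parametrize("radius", [3, 5, 8, 15])
    def test_disk_circularity_near_one(self, radius):
        img = np.zeros((64, 64))
        rr, cc = disk((32, 32), radius)
        img[rr, cc] = 10.0
        rec = measure_objects(segment_2d(img, None, 5.0, 1), 0.1)
        assert 0.9 <= rec.circularity[0] <= 1.1
        assert rec.equivalent_radius_um[0] == pytest.approx(radius * 0.1, rel=0.1)

    def test_integrated_intensity_of_unit_image_equals_pixel_count(self):
        img = np.zeros((16, 16))
        img[2:8, 2:8] = 10.0
        out = segment_2d(img, None, 5.0, 1)
        rec = measure_objects(out, 0.1, channel_images={"u": np.ones((16, 16))})
        assert rec.intint_u[0] == rec.n_px[0]

    def test_volume_and_z_centroid(self):
        vol = np.zeros((6, 10, 10))
        vol[1:5, 1:5, 1:5] = 10.0
        out = segment_3d(vol, None, 5.0, 64)
        rec = measure_objects(out, 0.1, z_step_um=0.25)
        assert rec.volume_um3[0] == pytest.approx(64 * 0.1**2 * 0.25)
        assert rec.centroid_z_um[0] == pytest.approx(2.5 * 0.25)

    def test_missing_geometry_is_configuration_error(self):
        vol = np.zeros((6, 10, 10))
        vol[1:5, 1:5, 1:5] = 10.0
        out = segment_3d(vol, None, 5.0, 64)
        with pytest.raises(ConfigurationError):
            measure_objects(out, 0.1)  # no z step for a 3D object


class TestDetectionVsGroundTruth:
    def test_sparse_noise_free_scene_recovered(self):
        p = SimParams(seed=5, n_aggregates=12, bg_sd=0.0, n_condensates=0,
                      light_schedule=[(1, 2)], n_frames=3)
        stack, roi, truth = simulate_cell(p)
        frame = stack.frame(0, "polyQ")
        thr = p.bg_mean + 2.5 * 20.0  # the margin the default noise level implies
        out = segment_2d(frame, roi, thr, 16)
        rec = measure_objects(out, stack.pixel_size_um)
        ta = truth.aggregates_at(0)
        assert len(rec) == (ta.area_um2 >= 0.116).sum()
        det = rec[["centroid_y_um", "centroid_x_um"]].to_numpy()
        for r in ta.itertuples():
            if r.area_um2 < 0.2:
                continue
            d = np.hypot(det[:, 0] - r.y_um, det[:, 1] - r.x_um)
            j = int(np.argmin(d))
            assert d[j] <= stack.pixel_size_um  # centroid within 1 px
            assert rec.area_um2[j] == pytest.approx(r.area_um2, rel=0.20)
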