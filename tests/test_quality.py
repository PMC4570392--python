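import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uavweed import (
    OrthoImage,
    PointPair,
    asprs_test,
    band_stats,
    class1_limit,
    compare_stats,
    measure_pairs,
    nn_resample,
    resample_spec,
    rmse,
)
from uavweed.quality import InsufficientPointsError


def _pairs(dx_cm=0.0, dy_cm=0.0, n=20):
    d = (dx_cm / 100.0, dy_cm / 100.0)
    return [PointPair(i, (i * 10.0, i * 7.0), (i * 10.0 + d[0], i * 7.0 + d[1]))
            for i in range(n)]


class TestRMSE:
    @pytest.mark.parametrize(
        "values,expected",
        [([0, 0, 0], 0.0), ([3, 4], 3.5355339), ([2.5] * 7, 2.5)],
    )
    def test_known_values(self, values, expected):
        assert rmse(values) == pytest.approx(expected, abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([])

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=30),
           st.floats(1.0, 5.0))
    @settings(derandomize=True, max_examples=50)
    def test_scaling_property(self, values, scale):
        assert rmse([v * scale for v in values]) == pytest.approx(
            scale * rmse(values), rel=1e-9, abs=1e-9
        )


class TestASPRS:
    def test_class1_limit_anchor_and_scaling(self):
        assert class1_limit(50) == 1.25
        assert class1_limit(100) == 2.50
        assert class1_limit(1) == 0.025
        with pytest.raises(ValueError):
            class1_limit(0)

    @pytest.mark.parametrize(
        "dx,dy,expected_class",
        [(0.0, 0.0, 1), (1.2, 1.1, 1), (2.0, 0.5, 2), (3.4, 0.2, 3),
         (4.0, 0.0, "fail")],
    )
    def test_classification_at_scale_fifty(self, dx, dy, expected_class):
        rep = asprs_test(_pairs(dx, dy), 50)
        assert rep.achieved_class == expected_class

    def test_worst_axis_determines_quality(self):
        rep = asprs_test(_pairs(dx_cm=0.4, dy_cm=2.0), 50)
        assert rep.limiting_axis == "Y"
        assert rep.achieved_class == 2

    def test_under_twenty_points_is_hard_error(self):
        with pytest.raises(InsufficientPointsError):
            asprs_test(_pairs(n=19), 50)

    @given(st.floats(0.1, 3.0), st.floats(1.0, 4.0))
    @settings(derandomize=True, max_examples=40)
    def test_inflating_discrepancies_never_improves_class(self, d, lam):
        order = {1: 1, 2: 2, 3: 3, "fail": 4}
        before = asprs_test(_pairs(d, d), 50).achieved_class
        after = asprs_test(_pairs(d * lam, d * lam), 50).achieved_class
        assert order[after] >= order[before]


class TestBandStats:
    def test_constant_image(self):
        img = OrthoImage({"R": np.full((10, 10), 7, np.uint8)}, 1.0)
        assert band_stats(img)["R"] == (7.0, 0.0)

    def test_compare_identical_is_zero(self, rgb_image):
        deltas = compare_stats(rgb_image, rgb_image)
        assert all(d["delta_mean"] == 0.0 and d["delta_sd"] == 0.0
                   for d in deltas.values())

    def test_band_mismatch_rejected(self, rgb_image, rnir_image):
        with pytest.raises(ValueError):
            compare_stats(rgb_image, rnir_image)

    def test_nn_resample_preserves_band_statistics(self, rgb_image):
        # the spectral-preservation property behind identical band means of
        # source and nearest-neighbour resampled imagery
        rs = nn_resample(rgb_image, resample_spec(1.07, 3.25))
        deltas = compare_stats(rgb_image, rs)
        for d in deltas.values():
            assert abs(d["delta_mean"]) < 1.0
            assert abs(d["delta_sd"]) < 1.0


class TestMeasurePairs:
    def test_identical_images_give_zero_discrepancy(self, compact_field,
                                                    rgb_image):
        _, truth = compact_field
        pairs, missing = measure_pairs(rgb_image, rgb_image,
                                       truth.control_points,
                                       marker_size_m=truth.marker_size_m)
        assert not missing and len(pairs) == len(truth.control_points)
        assert rmse([p.test_xy[0] - p.reference_xy[0] for p in pairs]) == 0.0

    def test_constructed_one_pixel_shift_in_x(self, compact_field, rgb_image):
        _, truth = compact_field
        shifted = {
            name: np.pad(arr, ((0, 0), (1, 0)), mode="edge")[:, :-1]
            for name, arr in rgb_image.bands.items()
        }
        test = OrthoImage(shifted, rgb_image.gsd_cm, rgb_image.origin_xy)
        pairs, missing = measure_pairs(rgb_image, test, truth.control_points,
                                       marker_size_m=truth.marker_size_m)
        assert not missing
        dx_cm = np.array([(p.test_xy[0] - p.reference_xy[0]) * 100
                          for p in pairs])
        dy_cm = np.array([(p.test_xy[1] - p.reference_xy[1]) * 100
                          for p in pairs])
        assert dx_cm == pytest.approx(rgb_image.gsd_cm, abs=0.05)
        assert np.abs(dy_cm).max() < 0.05

    def test_occluded_marker_reported_missing(self, compact_field, rgb_image):
        _, truth = compact_field
        cp = truth.control_points[0]
        damaged = rgb_image.copy()
        g = rgb_image.gsd_m
        r, c = int(cp.y / g), int(cp.x / g)
        for arr in damaged.bands.values():
            arr[max(0, r - 40):r + 40, max(0, c - 40):c + 40] = 100
        pairs, missing = measure_pairs(rgb_image, damaged, truth.control_points,
                                       marker_size_m=truth.marker_size_m)
        assert missing == [cp.id]
        assert len(pairs) == len(truth.control_points) - 1
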