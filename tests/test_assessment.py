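import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uavweed import (
    concordance,
    field_weed_cover,
    frame_weed_cover,
    threshold_series,
    treatment_decision,
    treatment_map,
)
from uavweed.assessment import NO_TREATMENT, TREATMENT
from uavweed.obia import ClassifiedMap
from uavweed.synthetic import WEED, SamplingFrame


def _map(classes, gsd_cm=10.0):
    return ClassifiedMap(classes=np.asarray(classes, np.uint8), gsd_cm=gsd_cm)


class TestThresholdSeries:
    def test_seven_values_zero_to_fifteen_step_two_point_five(self):
        ts = threshold_series()
        assert len(ts) == 7
        assert ts[0] == 0.0 and ts[-1] == 15.0
        assert np.allclose(np.diff(ts), 2.5)


class TestFrameWeedCover:
    def test_extreme_and_half_covers(self):
        frame = SamplingFrame(1, 0.0, 0.0, 1.0, 3, 0.0)
        all_weed = _map(np.full((10, 10), WEED))
        assert frame_weed_cover(all_weed, frame) == 100.0
        assert frame_weed_cover(_map(np.zeros((10, 10))), frame) == 0.0
        half = np.zeros((10, 10))
        half[:5] = WEED
        assert frame_weed_cover(_map(half), frame) == 50.0

    def test_pixel_centre_in_frame_rule(self):
        # 20 x 20 px at 10 cm; frame over x,y in [0.55, 1.55): pixel centres
        # (c + 0.5) * 0.1 in that interval are cols 5..14, a 10 x 10 window;
        # the weed block occupies rows/cols 6..15, so 9 x 9 of the 100
        # window pixels are weed
        classes = np.zeros((20, 20))
        classes[6:16, 6:16] = WEED
        frame = SamplingFrame(1, 0.55, 0.55, 1.0, 3, 0.0)
        assert frame_weed_cover(_map(classes), frame) == 81.0

    def test_frame_outside_raster_rejected(self):
        frame = SamplingFrame(1, 50.0, 50.0, 1.0, 0, 0.0)
        with pytest.raises(ValueError):
            frame_weed_cover(_map(np.zeros((10, 10))), frame)


class TestTreatmentDecision:
    @pytest.mark.parametrize(
        "cover,threshold,expected",
        [
            (0.0, 0.0, NO_TREATMENT),  # no weed presence -> never treat
            (0.1, 0.0, TREATMENT),  # presence rule at threshold zero
            (15.0, 15.0, NO_TREATMENT),  # strictly greater than
            (15.1, 15.0, TREATMENT),
        ],
    )
    def test_strict_exceedance_rule(self, cover, threshold, expected):
        assert treatment_decision(cover, threshold) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            treatment_decision(101.0, 5.0)
        with pytest.raises(ValueError):
            treatment_decision(5.0, -1.0)

    @given(st.lists(st.floats(0, 100), min_size=4, max_size=40))
    @settings(derandomize=True, max_examples=50)
    def test_treated_count_nonincreasing_in_threshold(self, covers):
        covers = dict(enumerate(covers))
        counts = [
            sum(d == TREATMENT
                for d in treatment_map(covers, t).decisions.values())
            for t in threshold_series()
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestConcordance:
    def test_identical_covers_match_everywhere(self):
        covers = {i: float(i * 3) for i in range(32)}
        rep = concordance(covers, covers)
        assert rep.match_pct == [100.0] * 7

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = {i: float(v) for i, v in enumerate(rng.uniform(0, 30, 32))}
        b = {i: float(v) for i, v in enumerate(rng.uniform(0, 30, 32))}
        assert concordance(a, b).match_pct == concordance(b, a).match_pct

    def test_all_decisions_differ_gives_zero(self):
        a = {i: 0.0 for i in range(8)}
        b = {i: 99.0 for i in range(8)}
        rep = concordance(a, b, thresholds=[5.0])
        assert rep.match_pct == [0.0]

    def test_partial_agreement_count(self):
        a = {i: 10.0 for i in range(8)}
        b = {i: (10.0 if i < 6 else 1.0) for i in range(8)}
        rep = concordance(a, b, thresholds=[5.0])
        assert rep.match_pct == [75.0]

    def test_frame_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance({1: 0.0}, {2: 0.0})

    def test_per_category_and_quadrants(self):
        cats = {i: (0 if i < 4 else 3) for i in range(8)}
        a = {i: (0.0 if i < 4 else 30.0) for i in range(8)}
        b = dict(a)
        b[0] = 20.0  # one category-0 frame flips to Treatment everywhere
        rep = concordance(a, b, thresholds=[5.0], categories=cats)
        assert rep.per_category[0] == 75.0
        assert rep.per_category[3] == 100.0
        assert rep.quadrant_counts[(0, 5.0)] == {"TT": 0, "TN": 0, "NT": 1,
                                                 "NN": 3}
        assert rep.quadrant_counts[(3, 5.0)] == {"TT": 4, "TN": 0, "NT": 0,
                                                 "NN": 0}

    def test_concordance_beats_permuted_frames(self, compact_field, rnir_image):
        # paired 60 m maps agree at least as well as after shuffling one
        # side's frame identities
        from uavweed import nn_resample, render_image, resample_spec, run_obia

        scenario, truth = compact_field
        rs = nn_resample(rnir_image, resample_spec(1.6, 3.25))
        real = render_image(truth, scenario, 3.25, "R-NIR")
        m_rs, m_real = run_obia(rs), run_obia(real)
        a = {f.id: frame_weed_cover(m_real, f) for f in truth.frames}
        b = {f.id: frame_weed_cover(m_rs, f) for f in truth.frames}
        rep = concordance(a, b)
        rng = np.random.default_rng(0)
        ids = list(b)
        perm = dict(zip(ids, rng.permutation(ids)))
        b_perm = {i: b[perm[i]] for i in ids}
        rep_perm = concordance(a, b_perm)
        assert np.mean(rep.match_pct) >= np.mean(rep_perm.match_pct)


class TestFieldWeedCover:
    def test_constructed_quarters(self):
        classes = np.zeros((10, 10))
        assert field_weed_cover(_map(classes)) == 0.0
        classes[:5, :5] = WEED
        assert field_weed_cover(_map(classes)) == 25.0
        classes[:, :] = WEED
        assert field_weed_cover(_map(classes)) == 100.0

    def test_common_area_mask(self):
        classes = np.zeros((10, 10))
        classes[:5] = WEED
        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        assert field_weed_cover(_map(classes), mask) == 100.0
        with pytest.raises(ValueError):
            field_weed_cover(_map(classes), np.zeros((10, 10), bool))
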