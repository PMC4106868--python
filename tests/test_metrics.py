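"""Peak detection, spacing, lineage tracking and branch counting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from branchrd.metrics import (
    PeakSet,
    count_side_branches,
    detect_peaks,
    peak_spacing,
    track_splits,
)


def gaussian_bump(shape, center, sigma=1.5, height=1.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return height * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)
    )


class TestDetectPeaks:
    def test_flat_field_has_no_peaks(self):
        peaks = detect_peaks(np.full((20, 20), 2.0), threshold=0.5, dx=0.3)
        assert len(peaks) == 0

    def test_two_separated_bumps(self):
        field = gaussian_bump((30, 90), (15, 20)) + gaussian_bump(
            (30, 90), (15, 20 + 67)
        )
        # bumps ~20 space units apart at dx = 0.3
        peaks = detect_peaks(field, threshold=0.5, min_separation=5.0, dx=0.3)
        assert len(peaks) == 2
        np.testing.assert_allclose(
            sorted(peaks.xs), [20 * 0.3, 87 * 0.3], atol=0.3
        )

    def test_close_maxima_merge_keeping_higher(self):
        field = gaussian_bump((30, 90), (15, 20), height=1.0) + gaussian_bump(
            (30, 90), (15, 87), height=2.0
        )
        peaks = detect_peaks(field, threshold=0.5, min_separation=30.0, dx=0.3)
        assert len(peaks) == 1
        assert peaks.heights[0] == pytest.approx(2.0, rel=1e-2)

    def test_plateau_merges_to_single_centroid(self):
        field = np.zeros((15, 15))
        field[6:9, 6:9] = 1.0
        peaks = detect_peaks(field, threshold=0.5, min_separation=0.9, dx=1.0)
        assert len(peaks) == 1
        np.testing.assert_allclose(peaks.centroids[0], [7.0, 7.0])

    def test_nonfinite_field_rejected(self):
        field = np.zeros((5, 5))
        field[2, 2] = np.inf
        with pytest.raises(ValueError):
            detect_peaks(field, threshold=0.5)

    @given(scale=st.floats(0.5, 10.0))
    def test_detection_invariant_under_field_scaling(self, scale):
        field = gaussian_bump((20, 40), (10, 10)) + gaussian_bump(
            (20, 40), (10, 30), height=0.8
        )
        base = detect_peaks(field, threshold=0.3, min_separation=0.9, dx=0.3)
        scaled = detect_peaks(
            field * scale, threshold=0.3 * scale, min_separation=0.9, dx=0.3
        )
        assert len(base) == len(scaled)
        np.testing.assert_allclose(scaled.centroids, base.centroids)


class TestSpacing:
    def test_regular_gaps(self):
        peaks = PeakSet(
            centroids=np.array([[10.0, 0.0], [20.0, 1.0], [30.0, 0.5]]),
            heights=np.ones(3),
        )
        stats = peak_spacing(peaks)
        np.testing.assert_allclose(stats.gaps, [10.0, 10.0])
        assert stats.mean == pytest.approx(10.0)

    def test_single_peak_spacing_undefined(self):
        peaks = PeakSet(np.array([[5.0, 5.0]]), np.ones(1))
        assert peak_spacing(peaks) is None

    def test_projection_axis(self):
        peaks = PeakSet(
            centroids=np.array([[0.0, 1.0], [0.0, 4.0], [0.0, 9.0]]),
            heights=np.ones(3),
        )
        stats = peak_spacing(peaks, axis="y")
        np.testing.assert_allclose(stats.gaps, [3.0, 5.0])


class TestTrackSplits:
    @staticmethod
    def _pk(*xy):
        return PeakSet(np.asarray(xy, dtype=float), np.ones(len(xy)))

    def test_single_moving_peak_that_divides(self):
        snaps = [
            (0, self._pk((10.0, 5.0))),
            (1, self._pk((10.5, 5.0))),
            (2, self._pk((11.0, 4.6), (11.0, 5.4))),
            (3, self._pk((11.5, 4.2), (11.5, 5.8))),
        ]
        events, maxgen = track_splits(snaps, match_radius=1.5)
        assert len(events) == 1
        assert maxgen == 1
        assert events[0].step == 2
        assert events[0].generation == 1

    def test_two_generations(self):
        snaps = [
            (0, self._pk((0.0, 5.0))),
            (1, self._pk((0.5, 4.5), (0.5, 5.5))),
            (2, self._pk((1.0, 4.0), (1.0, 5.0), (1.0, 6.0))),
        ]
        # frame 2: lower child splits again (4.5 -> 4.0 & 5.0)
        events, maxgen = track_splits(snaps, match_radius=0.9)
        assert maxgen == 2

    def test_independent_births_do_not_split(self):
        snaps = [
            (0, self._pk((5.0, 5.0))),
            (1, self._pk((5.0, 5.0), (20.0, 5.0))),
            (2, self._pk((5.0, 5.0), (20.0, 5.0), (40.0, 5.0))),
        ]
        events, maxgen = track_splits(snaps, match_radius=2.0)
        assert events == []
        assert maxgen == 0


class TestSideBranches:
    def test_straight_bar_has_no_branches(self):
        Y = np.zeros((21, 60))
        Y[9:12, 5:55] = 1.0
        stats = count_side_branches(Y)
        assert stats.count == 0

    def test_comb_with_three_teeth_one_side(self):
        # teeth shorter than the bar's end margins, so the longest geodesic
        # (the main-path convention) is the bar itself
        Y = np.zeros((30, 60))
        Y[14:17, 2:58] = 1.0
        for j in (16, 30, 44):
            Y[5:14, j : j + 3] = 1.0
        stats = count_side_branches(Y)
        assert stats.count == 3
        assert stats.one_sided
        assert stats.alternation_index == 0.0

    def test_alternating_fishbone_scores_one(self):
        Y = np.zeros((30, 72))
        Y[14:17, 2:70] = 1.0
        for idx, j in enumerate((14, 28, 42, 56)):
            if idx % 2 == 0:
                Y[5:14, j : j + 3] = 1.0
            else:
                Y[17:26, j : j + 3] = 1.0
        stats = count_side_branches(Y)
        assert stats.count == 4
        assert stats.alternation_index == pytest.approx(1.0)
        assert not stats.one_sided

    def test_symmetric_pairs_score_zero(self):
        Y = np.zeros((30, 60))
        Y[14:17, 2:58] = 1.0
        for j in (16, 40):
            Y[5:14, j : j + 3] = 1.0
            Y[17:26, j : j + 3] = 1.0
        stats = count_side_branches(Y)
        assert stats.count == 4
        assert stats.n_symmetric_pairs == 2
        assert stats.alternation_index == 0.0

    def test_empty_mask_counts_zero(self):
        stats = count_side_branches(np.zeros((10, 10)))
        assert stats.count == 0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_branch_count_invariant_under_right_angle_rotation(self, k):
        Y = np.zeros((40, 40))
        Y[19:22, 2:38] = 1.0
        for j in (12, 26):
            Y[11:19, j : j + 3] = 1.0
        base = count_side_branches(Y).count
        rotated = count_side_branches(np.rot90(Y, k)).count
        assert rotated == base
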