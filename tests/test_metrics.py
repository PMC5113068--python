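"""Track mapping and the four accuracy metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from helpers import disk_mask

from masktrack.metrics import (
    TrackSet,
    alpha,
    beta,
    count_tp_fp_fn,
    evaluate,
    jaccard,
    map_tracks_by_distance,
    map_tracks_by_overlap,
)


def _ts(rows):
    """rows: (track_id, frame, row, col) tuples."""
    return TrackSet(pd.DataFrame(rows, columns=["track_id", "frame", "row", "col"]))


def _straight_track(track_id, n_frames, row0, col0, drow=0.0, dcol=0.0):
    return [
        (track_id, f, row0 + f * drow, col0 + f * dcol) for f in range(n_frames)
    ]


class TestTrackSet:
    def test_duplicate_sample_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _ts([(1, 0, 0, 0), (1, 0, 1, 1)])

    def test_links_count_consecutive_samples_only(self):
        ts = _ts([(1, 0, 0, 0), (1, 1, 0, 0), (1, 3, 0, 0)])
        assert ts.links() == {(1, 0)}  # the 1->3 gap is not a decision


class TestDistanceMapping:
    def test_identical_sets_pair_everything_at_zero(self):
        ts = _ts(_straight_track(1, 5, 10, 10, dcol=2))
        pairing = map_tracks_by_distance(ts, ts, epsilon=5)
        assert pairing.paired_est_positions() == 5
        assert all(d == 0 for ps in pairing.pairs.values() for _, _, d in ps)

    def test_six_pixels_apart_is_not_paired_at_epsilon_five(self):
        ref = _ts([(1, 0, 10.0, 10.0)])
        est = _ts([(9, 0, 10.0, 16.0)])
        pairing = map_tracks_by_distance(ref, est, epsilon=5)
        assert pairing.pairs == {}

    def test_assignment_beats_greedy_pairing(self):
        # greedy pairs ref A to the nearest est (dist 1), stranding ref B at
        # distance 4.8; the optimal pairing totals 2 + 2.2 < 1 + 4.8
        ref = [(1, 0, 0.0, 0.0), (2, 0, 0.0, 3.0)]
        est = [(11, 0, 0.0, 1.0), (12, 0, 0.0, -2.0)]
        pairing = map_tracks_by_distance(_ts(ref), _ts(est), epsilon=5)
        got = {(r, e) for r, e, _ in pairing.pairs[0]}
        # brute-force oracle over both complete pairings
        totals = {}
        for perm in itertools.permutations([11, 12]):
            totals[perm] = sum(
                abs(rc - {11: 1.0, 12: -2.0}[e])
                for (_, _, _, rc), e in zip(ref, perm)
            )
        best = min(totals, key=totals.get)
        assert got == {(1, best[0]), (2, best[1])}

    def test_track_level_pairing_follows_accumulated_counts(self):
        ref = _ts(_straight_track(1, 10, 20, 20))
        est = _ts(
            _straight_track(5, 6, 20, 20) + _straight_track(6, 3, 60, 60)
        )
        pairing = map_tracks_by_distance(ref, est, epsilon=5)
        assert pairing.track_pairs == {1: 5}


class TestOverlapMapping:
    def test_identical_masks_pair_all_objects(self):
        masks = [disk_mask((40, 40), [(20, 20, 1, 5), (10, 30, 2, 4)], i) for i in range(3)]
        pairing = map_tracks_by_overlap(masks, masks)
        for ps in pairing.pairs.values():
            assert {(r, e) for r, e, _ in ps} == {(1, 1), (2, 2)}

    def test_non_mutual_maximum_stays_unpaired(self):
        # est 9 overlaps ref 1 most, but ref 1's own maximum is est 8
        ref = disk_mask((30, 60), [(15, 20, 1, 8)])
        est = np.zeros((30, 60), dtype=int)
        est[7:24, 12:21] = 8   # big overlap with ref 1
        est[7:24, 22:27] = 9   # smaller overlap with ref 1, nothing else
        from masktrack.io import LabeledMask

        pairing = map_tracks_by_overlap([ref], [LabeledMask(est, 0)])
        pairs = {(r, e) for r, e, _ in pairing.pairs.get(0, [])}
        assert pairs == {(1, 8)}  # 9 is unpaired despite overlapping only 1

    def test_zero_overlap_frames_have_no_pairs(self):
        a = [disk_mask((40, 40), [(10, 10, 1, 4)], 0)]
        b = [disk_mask((40, 40), [(30, 30, 1, 4)], 0)]
        assert map_tracks_by_overlap(a, b).pairs == {}

    def test_mismatched_frame_counts_rejected(self):
        a = [disk_mask((40, 40), [(10, 10, 1, 4)], i) for i in range(2)]
        with pytest.raises(ValueError, match="frame counts"):
            map_tracks_by_overlap(a, a[:1])


class TestCounting:
    def test_perfect_estimate_has_no_errors(self):
        ref = _ts(_straight_track(1, 6, 10, 10) + _straight_track(2, 6, 30, 30))
        pairing = map_tracks_by_distance(ref, ref, epsilon=5)
        tp, fp, fn = count_tp_fp_fn(pairing, "decisions")
        assert (tp, fp, fn) == (10, 0, 0)  # 2 tracks x 5 links
        tp, fp, fn = count_tp_fp_fn(pairing, "whole_track")
        assert (tp, fp, fn) == (2, 0, 0)

    def test_missing_track_counts_links_and_track(self):
        ref = _ts(_straight_track(1, 10, 10, 10) + _straight_track(2, 10, 40, 40))
        est = _ts(_straight_track(7, 10, 10, 10))  # track 2 entirely missed
        pairing = map_tracks_by_distance(ref, est, epsilon=5)
        tp, fp, fn = count_tp_fp_fn(pairing, "decisions")
        assert (tp, fp, fn) == (9, 0, 9)
        tp, fp, fn = count_tp_fp_fn(pairing, "whole_track")
        assert (tp, fp, fn) == (1, 0, 1)

    def test_spurious_track_counts_fp_links(self):
        ref = _ts(_straight_track(1, 10, 10, 10))
        est = _ts(_straight_track(7, 10, 10, 10) + _straight_track(8, 4, 50, 50))
        pairing = map_tracks_by_distance(ref, est, epsilon=5)
        tp, fp, fn = count_tp_fp_fn(pairing, "decisions")
        assert (tp, fp, fn) == (9, 3, 0)

    def test_broken_link_breaks_the_whole_track(self):
        # one bad frame: decisions lose 2 links, whole-track loses the track
        ref = _ts(_straight_track(1, 10, 10, 10))
        est_rows = _straight_track(7, 10, 10, 10)
        est_rows[5] = (7, 5, 30.0, 30.0)  # displaced far beyond epsilon
        pairing = map_tracks_by_distance(ref, _ts(est_rows), epsilon=5)
        d = jaccard(*count_tp_fp_fn(pairing, "decisions"))
        w = jaccard(*count_tp_fp_fn(pairing, "whole_track"))
        assert w < d < 1.0
        assert w == 0.0


class TestMetricValues:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [(6, 0, 0, 1.0), (0, 3, 4, 0.0), (3, 1, 2, 0.5)],
    )
    def test_jaccard_ratio(self, tp, fp, fn, expected):
        assert jaccard(tp, fp, fn) == expected

    def test_jaccard_empty_vs_empty_is_one(self):
        assert jaccard(0, 0, 0) == 1.0

    def test_perfect_estimate_scores_one_everywhere(self):
        ref = _ts(_straight_track(1, 8, 10, 10, dcol=1.5))
        pairing = map_tracks_by_distance(ref, ref, epsilon=5)
        assert evaluate(pairing) == {
            "alpha": 1.0, "beta": 1.0, "jaccard": 1.0, "jaccard_theta": 1.0
        }

    def test_empty_estimate_scores_zero(self):
        ref = _ts(_straight_track(1, 8, 10, 10))
        est = _ts(_straight_track(9, 8, 200, 200))  # never within epsilon
        pairing = map_tracks_by_distance(ref, est, epsilon=5)
        assert alpha(pairing) == 0.0 and beta(pairing) == 0.0

    def test_spurious_track_leaves_alpha_but_lowers_beta(self):
        ref = _ts(_straight_track(1, 8, 10, 10))
        perfect = map_tracks_by_distance(ref, _ts(_straight_track(7, 8, 10, 10)), 5)
        padded = map_tracks_by_distance(
            ref,
            _ts(_straight_track(7, 8, 10, 10) + _straight_track(8, 5, 100, 100)),
            5,
        )
        assert alpha(padded) == alpha(perfect) == 1.0
        assert beta(padded) < beta(perfect)
        assert beta(padded) <= alpha(padded)

    def test_all_metrics_bounded_on_noisy_input(self, rng):
        ref_rows = [
            s for k in range(4) for s in _straight_track(k + 1, 10, 20 * k + 10, 10, dcol=2)
        ]
        est_rows = [
            (tid + 10, f, r + rng.normal(0, 2), c + rng.normal(0, 2))
            for tid, f, r, c in ref_rows
        ]
        pairing = map_tracks_by_distance(_ts(ref_rows), _ts(est_rows), epsilon=5)
        scores = evaluate(pairing)
        for value in scores.values():
            assert 0.0 <= value <= 1.0
        assert scores["beta"] <= scores["alpha"]

    def test_empty_reference_is_an_error(self):
        est = _ts(_straight_track(1, 3, 10, 10))
        ref = TrackSet(pd.DataFrame(columns=["track_id", "frame", "row", "col"]))
        pairing = map_tracks_by_distance(ref, est, epsilon=5)
        with pytest.raises(ValueError, match="empty"):
            alpha(pairing)
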