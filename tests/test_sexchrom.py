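"""Coverage classification, alignment filtering, and stratum segmentation."""

import numpy as np
import pytest

from karyoz.sexchrom import (
    AlignmentRecord,
    classify_differentiation,
    filter_alignments,
    normalize_to_autosomes,
    optimal_partition,
    segment_strata,
    tile_windows,
    windowed_coverage,
    windowed_identity,
    CoverageTrack,
)


class TestWindows:
    def test_exact_tiling(self):
        assert tile_windows(200_000, 100_000) == [(0, 100_000), (100_000, 200_000)]

    def test_half_window_tail_merges_into_previous(self):
        wins = tile_windows(250_000, 100_000)
        assert wins == [(0, 100_000), (100_000, 250_000)]

    def test_long_tail_kept_as_own_window(self):
        wins = tile_windows(260_000, 100_000)
        assert wins == [(0, 100_000), (100_000, 200_000), (200_000, 260_000)]

    def test_uniform_depth_gives_constant_track(self):
        track = windowed_coverage(np.full(300_000, 30.0), 100_000)
        assert np.allclose(track.depth, 30.0)

    def test_stepped_depth_recovered_per_window(self):
        depth = np.concatenate([np.full(100_000, 10.0), np.full(100_000, 20.0)])
        track = windowed_coverage(depth, 100_000)
        assert np.allclose(track.depth, [10.0, 20.0])

    def test_empty_depth_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            windowed_coverage(np.array([]), 100_000)


class TestNormalization:
    def test_window_equal_to_autosomal_median_maps_to_one(self):
        z = windowed_coverage(np.full(200_000, 30.0), 100_000)
        auto = windowed_coverage(np.full(400_000, 30.0), 100_000)
        assert np.allclose(normalize_to_autosomes(z, [auto]).depth, 1.0)

    def test_zero_autosomal_median_rejected(self):
        z = windowed_coverage(np.full(200_000, 30.0), 100_000)
        auto = windowed_coverage(np.zeros(200_000), 100_000)
        with pytest.raises(ValueError, match="median"):
            normalize_to_autosomes(z, [auto])

    def test_simulated_hemizygous_ratio_near_half(self, rng):
        # female Z: one copy over the differentiated region at half depth
        hemi = rng.poisson(15.0, size=1_000_000).astype(float)
        auto = rng.poisson(30.0, size=1_000_000).astype(float)
        zt = windowed_coverage(hemi, 100_000)
        at = windowed_coverage(auto, 100_000)
        ratio = normalize_to_autosomes(zt, [at]).depth
        se = np.sqrt(15.0 / 100_000) / 30.0
        assert np.all(np.abs(ratio - 0.5) <= 3 * se + 1e-3)


class TestDifferentiation:
    def track(self, ratios):
        wins = [(i * 100_000, (i + 1) * 100_000) for i in range(len(ratios))]
        return CoverageTrack("Z", wins, np.asarray(ratios, float))

    def test_hemizygous_then_par_with_boundary(self):
        res = classify_differentiation(self.track([0.5] * 10 + [1.0] * 5))
        assert [(s.label, s.start, s.end) for s in res.segments] == [
            ("hemizygous", 0, 1_000_000),
            ("PAR", 1_000_000, 1_500_000),
        ]
        assert res.par_boundaries == [1_000_000]

    def test_undifferentiated_chromosome_is_single_par_segment(self):
        res = classify_differentiation(self.track([1.0] * 8))
        assert len(res.segments) == 1 and res.segments[0].label == "PAR"

    def test_all_intermediate_flagged_ambiguous(self):
        res = classify_differentiation(self.track([0.75] * 6))
        assert res.ambiguous and res.segments[0].label == "ambiguous"

    def test_intermediate_windows_join_nearer_flank(self):
        res = classify_differentiation(self.track([0.5, 0.5, 0.7, 1.0, 1.0]))
        # 0.7 window sits one step from each flank; ties go to the nearest
        # classified window scanning distance, here the hemizygous side wins
        # on argmin order; either attachment keeps exactly two segments
        assert len(res.segments) == 2
        assert res.segments[0].label == "hemizygous"
        assert res.segments[1].label == "PAR"


class TestAlignmentFilter:
    @pytest.mark.parametrize(
        "length,identity,kept",
        [
            (64, 80.0, False),  # too short
            (65, 80.0, True),
            (100, 59.0, False),  # too diverged
            (100, 60.0, True),
            (100, 96.0, True),
            (100, 97.0, False),  # repeat-like
            (65, 60.0, True),
            (65, 96.0, True),
            (64, 59.0, False),
            (64, 60.0, False),
            (64, 96.0, False),
            (64, 97.0, False),
            (65, 59.0, False),
            (65, 97.0, False),
        ],
    )
    def test_keep_drop_table(self, length, identity, kept):
        rec = AlignmentRecord(0, length, 0, length, length, identity)
        assert (filter_alignments([rec]) == [rec]) is kept

    def test_idempotent_and_order_preserving(self):
        recs = [
            AlignmentRecord(i * 100, i * 100 + 80, 0, 80, 80, ident)
            for i, ident in enumerate([70.0, 95.0, 61.0, 88.0])
        ]
        once = filter_alignments(recs)
        assert filter_alignments(once) == once == recs


class TestWindowedIdentity:
    def test_single_record_sets_window_identity(self):
        recs = [AlignmentRecord(10_000, 60_000, 0, 50_000, 50_000, 86.0)]
        _, ident = windowed_identity(recs, 100_000, 100_000)
        assert ident[0] == pytest.approx(86.0)

    def test_weighted_mean_of_two_records(self):
        recs = [
            AlignmentRecord(0, 100, 0, 100, 100, 80.0),
            AlignmentRecord(200, 500, 0, 300, 300, 90.0),
        ]
        _, ident = windowed_identity(recs, 100_000, 100_000)
        assert ident[0] == pytest.approx(87.5)

    def test_empty_window_is_missing(self):
        recs = [AlignmentRecord(0, 100, 0, 100, 100, 80.0)]
        _, ident = windowed_identity(recs, 300_000, 100_000)
        assert not np.isnan(ident[0]) and np.isnan(ident[1]) and np.isnan(ident[2])

    def test_record_spanning_windows_apportioned_by_overlap(self):
        recs = [AlignmentRecord(50_000, 150_000, 0, 100_000, 100_000, 70.0)]
        _, ident = windowed_identity(recs, 200_000, 100_000)
        assert ident[0] == pytest.approx(70.0) and ident[1] == pytest.approx(70.0)


def exhaustive_single_changepoint(y):
    """Oracle: best single split by trying every position."""
    best = (np.inf, None)
    for cut in range(1, len(y)):
        sse = ((y[:cut] - y[:cut].mean()) ** 2).sum() + (
            (y[cut:] - y[cut:].mean()) ** 2
        ).sum()
        if sse < best[0]:
            best = (sse, cut)
    return best


class TestSegmentation:
    def wins(self, n):
        return [(i * 100_000, (i + 1) * 100_000) for i in range(n)]

    def test_two_level_track_splits_at_true_boundary(self):
        y = np.array([70.0] * 20 + [86.0] * 20)
        segs = segment_strata(self.wins(40), y, max_segments=4)
        assert len(segs) == 2
        assert segs[0].last_window == 19 and segs[1].first_window == 20
        assert segs[0].mean_identity == pytest.approx(70.0)
        assert segs[1].mean_identity == pytest.approx(86.0)
        assert [s.label for s in segs] == ["S0", "S1"]

    def test_single_changepoint_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            y = np.concatenate(
                [rng.normal(70, 0.5, 15), rng.normal(80, 0.5, 25)]
            )
            sse_oracle, cut_oracle = exhaustive_single_changepoint(y)
            costs, starts = optimal_partition(y, 2)
            assert costs[1] == pytest.approx(sse_oracle)
            assert starts[1][1] == cut_oracle

    def test_constant_track_yields_one_segment(self):
        segs = segment_strata(self.wins(30), np.full(30, 75.0))
        assert len(segs) == 1 and segs[0].label == "S0"

    def test_cost_never_increases_with_more_segments(self, rng):
        y = rng.normal(80, 2.0, 60)
        costs, _ = optimal_partition(y, 8)
        assert all(a >= b - 1e-9 for a, b in zip(costs, costs[1:]))

    def test_boundaries_invariant_under_mirror(self, rng):
        y = np.concatenate([rng.normal(70, 0.3, 20), rng.normal(78, 0.3, 20),
                            rng.normal(86, 0.3, 20)])
        segs_f = segment_strata(self.wins(60), y)
        segs_r = segment_strata(self.wins(60), y[::-1])
        bounds_f = sorted(s.first_window for s in segs_f if s.first_window > 0)
        bounds_r = sorted(60 - s.first_window for s in segs_r if s.first_window > 0)
        assert bounds_f == sorted(bounds_r)

    def test_missing_windows_skipped(self):
        y = np.array([70.0] * 10 + [np.nan] * 3 + [86.0] * 10)
        segs = segment_strata(self.wins(23), y)
        assert len(segs) == 2
        assert segs[0].mean_identity == pytest.approx(70.0)
        assert segs[1].first_window == 13

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            segment_strata(self.wins(5), np.full(5, np.nan))
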