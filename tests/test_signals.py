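"""Percentile thresholds, signal calling/merging, population assignment,
interval overlap, and genome coverage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ldcontrast import (AnnotationInterval, SignalRegion, assign_population,
                        call_signals, coverage_summary, overlap_annotations,
                        percentile_threshold)
from ldcontrast.signals import UNASSIGNED, intervals_to_frame, regions_to_frame
from ldcontrast.varld_core import VarLDTrack

from conftest import toy_dataset


def make_track(std_scores, chrom="1", window_size=5, first_index_step=1,
               mid_step=1_000):
    n = len(std_scores)
    df = pd.DataFrame({
        "chromosome": chrom,
        "first_snp_index": np.arange(n) * first_index_step,
        "first_snp_bp": np.arange(n) * mid_step + 1,
        "last_snp_bp": np.arange(n) * mid_step + window_size * 100,
        "mid_bp": np.arange(n) * mid_step + 500,
        "raw_score": np.asarray(std_scores, float) + 10,
        "std_score": np.asarray(std_scores, float),
    })
    return VarLDTrack("POP1/POP2", window_size, 1, df)


class TestPercentileThreshold:
    def test_linear_interpolation_oracle(self):
        track = make_track(np.arange(1.0, 101.0))
        assert percentile_threshold(track, 99) == pytest.approx(99.01)

    def test_percentile_100_is_maximum(self):
        track = make_track([0.3, 2.0, -1.0])
        assert percentile_threshold(track, 100) == 2.0

    def test_normal_sample_999th(self):
        rng = np.random.default_rng(0)
        track = make_track(rng.standard_normal(10_000))
        assert percentile_threshold(track, 99.9) == pytest.approx(3.09, abs=0.15)

    def test_empty_track_raises(self):
        with pytest.raises(ValueError):
            percentile_threshold(make_track([]), 99)

    @given(st.floats(90, 99.99), st.floats(0.001, 9.9))
    def test_monotone_in_percentile(self, lo, delta):
        rng = np.random.default_rng(1)
        track = make_track(rng.standard_normal(500))
        hi = min(lo + delta, 100.0)
        assert percentile_threshold(track, lo) <= percentile_threshold(track, hi)


class TestCallSignals:
    def test_single_run_merges_into_one_region(self):
        track = make_track([0, 5, 6, 5, 0])
        regions = call_signals(track, 4.5)
        assert len(regions) == 1
        r = regions[0]
        assert r.n_windows == 3
        assert r.peak_std_score == 6.0
        assert r.start_bp == track.scores["mid_bp"].iloc[1]
        assert r.end_bp == track.scores["mid_bp"].iloc[3]

    def test_runs_separated_by_window_size_split(self):
        # flagged runs separated by >= window_size unflagged windows split
        w = 5
        std = np.zeros(20)
        std[2] = 9.0
        for gap in (w - 1, w):
            std2 = std.copy()
            std2[3 + gap] = 9.0
            regions = call_signals(make_track(std2, window_size=w), 8.0)
            # brute-force run-length oracle: one region iff index gap <= w
            expect = 1 if (3 + gap) - 2 <= w else 2
            assert len(regions) == expect

    def test_no_flagged_windows_empty_list(self):
        assert call_signals(make_track([0.0, 1.0]), 5.0) == []

    def test_threshold_nesting_property(self):
        rng = np.random.default_rng(2)
        track = make_track(rng.standard_normal(300))
        low = call_signals(track, 1.5)
        high = call_signals(track, 2.5)
        # every high-threshold region lies inside some low-threshold region
        for rh in high:
            assert any(rl.start_bp <= rh.start_bp and rh.end_bp <= rl.end_bp
                       for rl in low)
        assert len(low) <= (track.scores["std_score"] >= 1.5).sum()

    def test_regions_disjoint_in_window_index(self):
        rng = np.random.default_rng(3)
        track = make_track(rng.standard_normal(300))
        regions = call_signals(track, 1.0)
        regions.sort(key=lambda r: r.first_window_index)
        for r1, r2 in zip(regions, regions[1:]):
            assert r1.last_window_index < r2.first_window_index


class TestAssignPopulation:
    def _region(self, start, end):
        return SignalRegion("POP1/POP2", "1", start, end, 5.0, 1, 0, 0)

    def test_perfect_ld_population_wins(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 3, size=(40, 1)).astype(float)
        a = toy_dataset(np.repeat(base, 10, axis=1))
        b = toy_dataset(rng.integers(0, 3, size=(40, 10)).astype(float),
                        population="POP2")
        label, margin = assign_population(self._region(1, 20_000), a, b)
        assert label == "POP1"
        assert margin > 0.5

    def test_same_data_ties_to_first_label(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(40, 10)).astype(float)
        a = toy_dataset(g)
        b = toy_dataset(g, population="POP2")
        region = self._region(1, 20_000)
        with pytest.warns(UserWarning, match="tie"):
            label, margin = assign_population(region, a, b)
        assert label == "POP1"
        assert margin == 0.0
        assert region.assignment_tie

    def test_too_few_snps_unassigned(self):
        rng = np.random.default_rng(6)
        a = toy_dataset(rng.integers(0, 3, size=(40, 10)).astype(float))
        b = toy_dataset(rng.integers(0, 3, size=(40, 10)).astype(float),
                        population="POP2")
        label, margin = assign_population(self._region(900, 1100), a, b)
        assert label == UNASSIGNED
        assert np.isnan(margin)


class TestOverlapAnnotations:
    def _region(self, chrom, start, end):
        return SignalRegion("A/B", chrom, start, end, 5.0, 1, 0, 0)

    def test_inclusive_overlap_length(self):
        regions = [self._region("1", 100, 200)]
        ann = [AnnotationInterval("1", 150, 250, "geneA")]
        out = overlap_annotations(regions, ann)
        assert len(out) == 1
        assert out.loc[0, "overlap_bp"] == 51

    def test_abutting_intervals_do_not_overlap(self):
        regions = [self._region("1", 100, 200)]
        ann = [AnnotationInterval("1", 201, 300, "geneA")]
        assert overlap_annotations(regions, ann).empty

    def test_chromosome_mismatch_no_pair(self):
        regions = [self._region("1", 100, 200)]
        ann = [AnnotationInterval("2", 100, 200, "geneA")]
        assert overlap_annotations(regions, ann).empty

    def test_matches_base_by_base_brute_force(self):
        rng = np.random.default_rng(7)
        regions = [self._region(str(rng.integers(1, 3)),
                                int(s := rng.integers(1, 150)),
                                int(s + rng.integers(0, 60)))
                   for _ in range(30)]
        ann = [AnnotationInterval(str(rng.integers(1, 3)),
                                  int(s := rng.integers(1, 150)),
                                  int(s + rng.integers(0, 60)), f"g{k}")
               for k in range(60)]
        out = overlap_annotations(regions, ann)
        got = {(i, j): int(out_row.overlap_bp)
               for out_row in out.itertuples()
               for i, r in enumerate(regions)
               for j, g in enumerate(ann)
               if (out_row.region_start_bp == r.start_bp
                   and out_row.region_end_bp == r.end_bp
                   and out_row.chromosome == r.chromosome
                   and out_row.name == g.name)}
        # brute force over single base positions
        for i, r in enumerate(regions):
            for j, g in enumerate(ann):
                if r.chromosome != g.chromosome:
                    continue
                bases = len(set(range(r.start_bp, r.end_bp + 1))
                            & set(range(g.start_bp, g.end_bp + 1)))
                if bases:
                    assert got[(i, j)] == bases


class TestCoverage:
    def _region(self, chrom, start, end):
        return SignalRegion("A/B", chrom, start, end, 5.0, 1, 0, 0)

    def test_fraction_of_genome(self):
        regions = [self._region("1", 1, 10_760_000)]
        lengths = {"1": 1_502_000_000, "2": 1_000_000_000}
        total, frac = coverage_summary(regions, lengths)
        assert total == 10_760_000
        assert frac * 100 == pytest.approx(0.43, abs=0.001)

    def test_empty_regions(self):
        assert coverage_summary([], {"1": 100}) == (0, 0.0)

    def test_union_semantics(self):
        regions = [self._region("1", 100, 200), self._region("1", 150, 250)]
        total, _ = coverage_summary(regions, {"1": 1000})
        assert total == 151

    def test_invariant_to_order_and_duplication(self):
        regions = [self._region("1", 100, 200), self._region("1", 150, 250),
                   self._region("2", 5, 10)]
        t1, _ = coverage_summary(regions, {"1": 1000, "2": 1000})
        t2, _ = coverage_summary(regions[::-1] + regions, {"1": 1000, "2": 1000})
        assert t1 == t2

    def test_region_exceeding_chromosome_raises(self):
        with pytest.raises(ValueError):
            coverage_summary([self._region("1", 50, 2000)], {"1": 1000})


def test_region_frame_round_trip():
    r = SignalRegion("A/B", "1", 10, 20, 5.5, 2, 0, 1,
                     assigned_population="A", assignment_margin=0.3)
    df = regions_to_frame([r])
    assert df.loc[0, "assigned_population"] == "A"
    assert df.loc[0, "peak_std_score"] == 5.5


def test_interval_validation():
    with pytest.raises(ValueError):
        AnnotationInterval("1", 10, 5, "bad")
    assert not intervals_to_frame([]).shape[0]
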