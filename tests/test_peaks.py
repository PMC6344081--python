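import numpy as np
import pytest
from scipy import stats

from chip4c.io import GenomicInterval
from chip4c.peaks import (
    CandidateWindow,
    NcisFactor,
    Peak,
    PeakCallingParams,
    call_peaks,
    estimate_ncis,
    exclude_by_other_condition,
    fdr_select,
    local_thresholds,
    merge_windows,
    PeakSet,
    poisson_threshold,
    refine_borders,
    strand_filter,
)
from chip4c.signal import ReadSet, extend_reads
from chip4c.simulate import ChipSimSpec, PlantedPeak, simulate_chip


def frag_set(intervals, fragment_size=300, library_size=None):
    rs = ReadSet.from_intervals(intervals, fragment_size=fragment_size)
    if library_size is not None:
        rs.library_size = library_size
    rs.extended = True
    return rs


class TestEstimateNcis:
    def test_identical_counts_give_unity(self, rng):
        bins = rng.poisson(2.0, 10_000)
        assert estimate_ncis(bins, bins).r == pytest.approx(1.0)

    def test_pure_scaling_recovers_half(self, rng):
        s = rng.poisson(2.0, 10_000) * 1  # noqa: keep ints
        assert estimate_ncis(s, 2 * s).r == pytest.approx(0.5)

    def test_background_depth_ratio_recovered(self, rng):
        # independent Poisson background at depth ratio 0.7
        s = rng.poisson(2.0, 100_000)
        c = rng.poisson(2.0 / 0.7, 100_000)
        r = estimate_ncis(s, c).r
        assert abs(r - 0.7) / 0.7 < 0.05

    def test_enriched_fraction_does_not_distort(self, rng):
        s = rng.poisson(2.0, 100_000)
        c = rng.poisson(2.0, 100_000)
        s[:1000] += rng.poisson(40.0, 1000)  # 1% enriched bins
        r = estimate_ncis(s, c).r
        assert abs(r - 1.0) < 0.05

    def test_empty_control_errors(self):
        with pytest.raises(ValueError, match="control library empty"):
            estimate_ncis(np.ones(10, int), np.zeros(10, int))


class TestPoissonThreshold:
    def test_zero_lambda_needs_one_read(self):
        assert poisson_threshold(0.0, 1e-5) == 1

    @pytest.mark.parametrize("lam", [0.5, 1.0, 5.0, 40.0])
    def test_matches_brute_force_tail_sum(self, lam):
        p = 1e-5
        k = poisson_threshold(lam, p)
        # brute-force: smallest k with sum_{j>=k} pmf(j) <= p
        tail = 1.0
        j = 0
        brute = None
        while brute is None:
            if tail <= p:
                brute = j
            tail -= stats.poisson.pmf(j, lam)
            j += 1
            assert j < 10_000
        assert k == brute

    def test_monotone_in_lambda(self):
        lams = np.linspace(0, 100, 400)
        ks = [poisson_threshold(l, 1e-5) for l in lams]
        assert all(a <= b for a, b in zip(ks, ks[1:]))


class TestLocalThresholds:
    def test_flat_control_is_homogeneous(self):
        # evenly spaced control fragments -> identical thresholds anywhere
        ctrl = frag_set(
            [GenomicInterval("chr1", s, s + 300) for s in range(0, 100_000, 50)]
        )
        params = PeakCallingParams()
        ncis = NcisFactor(r=1.0, bins_used=1, background_fraction=1.0)
        ts = {
            local_thresholds(ctrl, "chr1", pos, params, ncis, global_lambda=0.1)
            for pos in (30_000, 50_000, 70_000)
        }
        assert len(ts) == 1

    def test_hotspot_raises_threshold_only_nearby(self):
        base = [GenomicInterval("chr1", s, s + 300) for s in range(0, 200_000, 100)]
        hot = [GenomicInterval("chr1", 100_000 + k, 100_300 + k) for k in range(500)]
        ctrl = frag_set(base + hot)
        params = PeakCallingParams()
        ncis = NcisFactor(r=1.0, bins_used=1, background_fraction=1.0)
        t_in = local_thresholds(ctrl, "chr1", 100_200, params, ncis, 0.1)
        t_out = local_thresholds(ctrl, "chr1", 30_000, params, ncis, 0.1)
        assert t_in > t_out

    def test_empty_control_falls_back_to_global(self):
        ctrl = frag_set([GenomicInterval("chr1", 0, 300)])
        ctrl.reads = ctrl.reads.iloc[:0]
        params = PeakCallingParams()
        ncis = NcisFactor(r=1.0, bins_used=1, background_fraction=1.0)
        glam = 5.0
        assert local_thresholds(
            ctrl, "chr1", 50_000, params, ncis, glam
        ) == poisson_threshold(glam, params.p_threshold)


class TestStrandFilter:
    @pytest.mark.parametrize(
        "plus,minus,expected",
        [
            (30, 9, False),   # 3.33:1
            (30, 10, False),  # exactly 3:1 is not "less than"
            (29, 10, True),
            (10, 29, True),
            (0, 0, False),
            (5, 0, False),
        ],
    )
    def test_ratio_rule(self, plus, minus, expected):
        assert strand_filter(plus, minus) is expected


class TestMergeWindows:
    def c(self, start, end):
        return GenomicInterval("chr1", start, end)

    def test_gap_within_100_merges(self):
        merged = merge_windows([self.c(100, 200), self.c(250, 350)])
        assert merged == [self.c(100, 350)]

    def test_gap_of_101_stays_separate(self):
        merged = merge_windows([self.c(100, 200), self.c(301, 401)])
        assert len(merged) == 2

    def test_order_invariant(self, rng):
        ivs = [
            self.c(int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 10_000, 100), rng.integers(50, 400, 100))
        ]
        ref = merge_windows(ivs)
        perm = [ivs[i] for i in rng.permutation(len(ivs))]
        assert merge_windows(perm) == ref


class TestRefineBorders:
    def rect_sample(self, lo, hi, spacing=2):
        # dense point-fragment pileup with sharp edges
        return frag_set(
            [GenomicInterval("chr1", s, s + 1) for s in range(lo, hi, spacing)],
            fragment_size=300,
        )

    def test_planted_rectangle_borders_recovered(self):
        sample = self.rect_sample(10_000, 12_000)
        params = PeakCallingParams()
        refined = refine_borders(
            GenomicInterval("chr1", 9_950, 12_050), sample, threshold=10,
            params=params,
        )
        assert abs(refined.start - 10_000) <= params.window_size
        assert abs(refined.end - 12_000) <= params.window_size

    def test_uniform_signal_leaves_borders_unchanged(self):
        sample = self.rect_sample(0, 40_000)
        refined = refine_borders(
            GenomicInterval("chr1", 20_000, 21_000), sample, threshold=10,
            params=PeakCallingParams(),
        )
        assert (refined.start, refined.end) == (20_000, 21_000)

    def test_symmetric_peak_refines_symmetrically(self):
        # point pileup mirror-symmetric under p -> 21_999 - p, matching the
        # reflection that fixes the half-open interval [9_900, 12_100)
        pts = [p for p in range(10_000, 11_000, 2)]
        pts += [21_999 - p for p in pts]
        sample = frag_set(
            [GenomicInterval("chr1", p, p + 1) for p in sorted(pts)],
            fragment_size=300,
        )
        refined = refine_borders(
            GenomicInterval("chr1", 9_900, 12_100), sample, threshold=10,
            params=PeakCallingParams(),
        )
        left_offset = refined.start - 9_900
        right_offset = 12_100 - refined.end
        assert left_offset == right_offset


class TestFdrSelect:
    def mkpeak(self, p, fold=3.0):
        return Peak(
            interval=GenomicInterval("chr1", 0, 200), summit=100, best_p=p,
            q_value=1.0, log2_fold_ncis=fold, plus_count=10, minus_count=10,
        )

    def test_bh_arithmetic_rejects_marginal_peak(self):
        # q = 1e-9 * 1e6 / 1 = 1e-3 > 1e-5
        pvals = np.concatenate([[1e-9], np.ones(999_999)])
        out = fdr_select([self.mkpeak(1e-9)], pvals, fdr_threshold=1e-5)
        assert len(out) == 0

    def test_all_unit_pvalues_yield_nothing(self):
        out = fdr_select([self.mkpeak(1.0)], np.ones(1000), fdr_threshold=1e-5)
        assert len(out) == 0

    def test_strong_peak_survives(self):
        pvals = np.concatenate([[1e-13], np.ones(999)])
        out = fdr_select([self.mkpeak(1e-13)], pvals, fdr_threshold=1e-5)
        assert len(out) == 1
        assert out.peaks[0].q_value == pytest.approx(1e-10)

    def test_low_fold_peak_rejected_despite_significance(self):
        pvals = np.concatenate([[1e-13], np.ones(999)])
        out = fdr_select([self.mkpeak(1e-13, fold=1.5)], pvals, 1e-5)
        assert len(out) == 0

    def test_bh_matches_independent_step_up(self, rng):
        # independent step-up oracle vs the statsmodels-backed q-values
        pvals = rng.random(1000) ** 2
        m = len(pvals)
        order = np.argsort(pvals)
        oracle_sorted = np.minimum.accumulate(
            (pvals[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        peaks = [self.mkpeak(float(p)) for p in pvals[:50]]
        out = fdr_select(peaks, pvals, fdr_threshold=2.0, min_log2_fold=0.0)
        got = np.array([p.q_value for p in out.peaks])
        assert np.allclose(got, oracle[:50])


class TestExcludeByOtherCondition:
    def peakset(self):
        return PeakSet(
            peaks=[
                Peak(
                    interval=GenomicInterval("chr1", 10_000, 10_400),
                    summit=10_200, best_p=1e-12, q_value=1e-8,
                    log2_fold_ncis=3.0, plus_count=5, minus_count=5,
                )
            ]
        )

    def other_with_signal(self, value):
        # value = n/(1+3)/ (lib/1e6) / 1 kb  -> choose n for target value
        lib = 25_000_000
        n = int(round(value * 4 * (lib / 1e6)))
        frags = [GenomicInterval("chr1", 10_100 + k, 10_400 + k) for k in range(n)]
        return frag_set(frags, library_size=lib)

    def test_signal_above_cutoff_excluded(self):
        out = exclude_by_other_condition(self.peakset(), self.other_with_signal(0.80))
        assert len(out) == 0

    def test_signal_exactly_at_cutoff_retained(self):
        out = exclude_by_other_condition(self.peakset(), self.other_with_signal(0.76))
        assert len(out) == 1

    def test_empty_other_library_errors(self):
        empty = frag_set([GenomicInterval("chr1", 0, 300)], library_size=0)
        with pytest.raises(ValueError, match="library"):
            exclude_by_other_condition(self.peakset(), empty)


class TestCallPeaksProperties:
    GENOME = [("chr1", 1_000_000)]

    def simulate(self, seed, peaks=(), **kw):
        spec = ChipSimSpec(
            genome=self.GENOME, library_size=100_000,
            planted_peaks=list(peaks), seed=seed, **kw,
        )
        return simulate_chip(spec)

    def planted(self):
        return [
            PlantedPeak("chr1", pos, width=400, fold=10.0)
            for pos in range(100_000, 1_000_000, 120_000)
        ]

    def test_planted_peaks_found_and_shuffling_invariant(self, rng):
        sample, control, truth = self.simulate(3, self.planted())
        result = call_peaks(sample, control, self.GENOME)
        assert len(result) == len(truth)
        # shuffle read order: calling must not change
        shuffled = ReadSet(
            reads=sample.reads.sample(frac=1.0, random_state=1).reset_index(
                drop=True
            ),
            library_size=sample.library_size,
            fragment_size=sample.fragment_size,
        )
        result2 = call_peaks(shuffled, control, self.GENOME)
        assert [p.interval for p in result] == [p.interval for p in result2]

    def test_swapping_sample_and_control_yields_nothing(self):
        sample, control, _ = self.simulate(4, self.planted())
        result = call_peaks(control, sample, self.GENOME)
        assert len(result) == 0

    def test_peak_qvalues_dominate_pvalues(self):
        sample, control, _ = self.simulate(5, self.planted())
        result = call_peaks(sample, control, self.GENOME)
        assert all(p.q_value >= p.best_p for p in result)
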