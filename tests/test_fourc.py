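import numpy as np
import pytest
from scipy import stats

from chip4c.fourc import (
    FourCProfile,
    call_contacts,
    normalize_profiles,
    rank_window_test,
    read_fourc_table,
    remove_excluded_ends,
    running_trimmed_mean,
    write_fourc_table,
    _window_rank_stats,
)
from chip4c.simulate import FourCSimSpec, PlantedContact, simulate_fourc


def profile(counts, blind=None, positions=None, chrom="chr11"):
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    return FourCProfile(
        chrom=chrom,
        positions=positions if positions is not None else np.arange(n) * 1000 + 500,
        blind=blind if blind is not None else np.zeros(n, dtype=bool),
        counts=counts,
    )


class TestRemoveExcludedEnds:
    def test_removes_viewpoint_and_both_neighbours(self):
        p = profile(np.arange(10))
        out = remove_excluded_ends(p, int(p.positions[5]))
        assert len(out) == 7
        assert int(p.positions[5]) not in out.positions

    def test_edge_viewpoint_removes_two(self):
        p = profile(np.arange(10))
        out = remove_excluded_ends(p, int(p.positions[0]))
        assert len(out) == 8

    def test_idempotent(self):
        p = profile(np.arange(10))
        vp = int(p.positions[5])
        once = remove_excluded_ends(p, vp)
        twice = remove_excluded_ends(once, vp)
        assert np.array_equal(once.positions, twice.positions)

    def test_unknown_viewpoint_errors(self):
        with pytest.raises(ValueError, match="viewpoint"):
            remove_excluded_ends(profile(np.arange(10)), 123456)


class TestNormalizeProfiles:
    def test_identical_profiles_unchanged_up_to_library_scaling(self, rng):
        counts = rng.poisson(50, 200).astype(float)
        blind = rng.random(200) < 0.3
        a = profile(counts, blind)
        b = profile(counts.copy(), blind)
        na, nb = normalize_profiles(a, b)
        assert np.allclose(na.values, counts / counts.sum() * 1e6)
        assert np.allclose(na.values, nb.values)

    def test_sorted_blind_values_equalized(self, rng):
        # tie-free values: with ties the mid-rank convention averages
        # order-statistic means, so exact sorted equality holds only for
        # distinct values
        blind = rng.random(300) < 0.4
        a = profile(rng.lognormal(3.0, 1.0, 300), blind)
        b = profile(rng.lognormal(4.0, 1.0, 300), blind)
        na, nb = normalize_profiles(a, b)
        # undo library scaling to compare the quantile-normalized values
        va = na.values * a.library_size
        vb = nb.values * b.library_size
        assert np.allclose(np.sort(va[blind]), np.sort(vb[blind]))
        assert np.allclose(np.sort(va[~blind]), np.sort(vb[~blind]))

    def test_blind_and_nonblind_are_independent(self, rng):
        blind = rng.random(300) < 0.4
        counts_a = rng.poisson(30, 300).astype(float)
        counts_b = rng.poisson(60, 300).astype(float)
        a1, _ = normalize_profiles(profile(counts_a, blind), profile(counts_b, blind))
        # permuting the non-blind counts keeps the library size and must
        # leave the blind values untouched
        counts_a2 = counts_a.copy()
        idx = np.flatnonzero(~blind)
        counts_a2[idx] = counts_a2[rng.permutation(idx)]
        a2, _ = normalize_profiles(profile(counts_a2, blind), profile(counts_b, blind))
        assert np.allclose(a1.values[blind], a2.values[blind])

    def test_different_fragment_maps_rejected(self):
        a = profile(np.arange(10))
        b = profile(np.arange(10), positions=np.arange(10) * 1000 + 600)
        with pytest.raises(ValueError, match="fragment maps"):
            normalize_profiles(a, b)


class TestRunningTrimmedMean:
    def test_constant_window_returns_constant(self):
        assert np.allclose(running_trimmed_mean(np.full(21, 3.0)), 3.0)

    def test_single_outlier_is_trimmed(self):
        vals = np.full(21, 2.0)
        vals[10] = 1e6
        out = running_trimmed_mean(vals)
        assert out[10] == pytest.approx(2.0)

    def test_matches_sort_and_slice_oracle(self, rng):
        vals = rng.lognormal(0, 1, 200)
        out = running_trimmed_mean(vals, window=21, trim=0.10)
        for i in range(200):
            lo, hi = max(i - 10, 0), min(i + 11, 200)
            window = np.sort(vals[lo:hi])
            k = int(0.10 * len(window))
            expected = window[k: len(window) - k].mean()
            assert out[i] == pytest.approx(expected)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            running_trimmed_mean(np.ones(30), window=20)


class TestRankWindowTest:
    def normalized(self, va, vb):
        a = profile(va)
        b = profile(vb)
        a.values = np.asarray(va, dtype=float)
        b.values = np.asarray(vb, dtype=float)
        return a, b

    def test_identical_values_are_null(self):
        a, b = self.normalized(np.ones(30), np.ones(30))
        windows = rank_window_test(a, b)
        assert all(w.chi2 == 0 and w.p == 1.0 for w in windows)

    def test_complete_separation_is_strongly_significant(self):
        # A above B at all 21 ends: rank sum hits its extreme
        rng = np.random.default_rng(0)
        va = 10 + rng.random(21)
        vb = rng.random(21)
        o_a, o_b, chi2, p = _window_rank_stats(va, vb)
        assert (o_a, o_b) == (672.0, 231.0)
        # chi2 = (672 - 451.5)^2 / (21*21*43/12)
        assert chi2 == pytest.approx(220.5**2 / 1580.25)
        assert p < 1e-7

    def test_statistic_matches_permutation_oracle(self, rng):
        # exact two-sample permutation p for one window, Monte Carlo
        va = rng.lognormal(0, 1, 21) * 2.0
        vb = rng.lognormal(0, 1, 21)
        o_a, _, chi2, p = _window_rank_stats(va, vb)
        pooled = np.concatenate([va, vb])
        stat = []
        for _ in range(20_000):
            perm = rng.permutation(pooled)
            s, *_ = _window_rank_stats(perm[:21], perm[21:])
            stat.append(abs(s - 451.5))
        perm_p = (np.sum(np.asarray(stat) >= abs(o_a - 451.5)) + 1) / 20_001
        assert p == pytest.approx(perm_p, abs=0.02)

    def test_swapping_profiles_swaps_winners_keeps_p(self, rng):
        spec = FourCSimSpec(n_fragment_ends=300, seed=1)
        a, b, _ = simulate_fourc(spec)
        na, nb = normalize_profiles(a, b)
        w1 = rank_window_test(na, nb)
        w2 = rank_window_test(nb, na)
        assert np.allclose([w.p for w in w1], [w.p for w in w2])
        for x, y in zip(w1, w2):
            if x.trimmed_mean_a != x.trimmed_mean_b:
                assert x.winner != y.winner

    def test_invariant_to_monotone_transform(self, rng):
        spec = FourCSimSpec(n_fragment_ends=200, seed=2)
        a, b, _ = simulate_fourc(spec)
        na, nb = normalize_profiles(a, b)
        w1 = rank_window_test(na, nb)
        na.values = np.log1p(na.values) ** 3
        nb.values = np.log1p(nb.values) ** 3
        w2 = rank_window_test(na, nb)
        assert np.allclose([w.p for w in w1], [w.p for w in w2])


class TestCallContacts:
    def test_all_unit_pvalues_yield_nothing(self):
        a = profile(np.ones(50))
        a.values = np.ones(50)
        b = profile(np.ones(50))
        b.values = np.ones(50)
        windows = rank_window_test(a, b)
        assert call_contacts(windows) == []

    def test_single_small_p_among_many_is_called(self, rng):
        spec = FourCSimSpec(n_fragment_ends=1200, seed=3)
        a, b, _ = simulate_fourc(spec)
        na, nb = normalize_profiles(a, b)
        windows = rank_window_test(na, nb)
        windows[100].p = 1e-6
        regions = call_contacts(windows, fdr=0.01)
        assert any(r.n_windows >= 1 and r.min_q < 0.01 for r in regions)

    def test_planted_block_recovered_with_winner(self):
        spec = FourCSimSpec(
            n_fragment_ends=2000, seed=4,
            planted_contacts=[
                PlantedContact(start_index=1200, n_ends=30, fold=10.0, winner="B")
            ],
        )
        a, b, truth = simulate_fourc(spec)
        na, nb = normalize_profiles(a, b)
        regions = call_contacts(rank_window_test(na, nb), fdr=0.01)
        t = truth.iloc[0]
        hits = [
            r for r in regions
            if r.winner == "B" and r.start < t["end"] and t["start"] < r.end
        ]
        assert hits


class TestFourCTableIO:
    def test_round_trip(self, tmp_path, rng):
        spec = FourCSimSpec(n_fragment_ends=100, seed=5)
        a, b, _ = simulate_fourc(spec)
        p = tmp_path / "fourc.tsv"
        write_fourc_table(a, b, p)
        a2, b2 = read_fourc_table(p)
        assert np.array_equal(a.positions, a2.positions)
        assert np.array_equal(a.counts, a2.counts)
        assert np.array_equal(b.counts, b2.counts)
        assert np.array_equal(a.blind, a2.blind)
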