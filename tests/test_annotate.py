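import numpy as np
import pytest
from scipy import stats

from chip4c.annotate import (
    CATEGORIES,
    classify_peak_location,
    enhancer_overlap,
    fisher_enrichment,
    nearest_transcript_fc,
    normalize_expression,
)
from chip4c.io import ExpressionRecord, GenomicInterval
from helpers import make_gene


def peak_at(mid, width=200, chrom="chr1"):
    return GenomicInterval(chrom, mid - width // 2, mid + width // 2)


def brute_force_category(midpoint, genes, chrom="chr1"):
    """Literal re-statement of the distance rules, scanned over all genes."""
    best = "intergenic"
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.strand == "+":
            d_up, d_down = g.tss - midpoint, midpoint - g.tes
        else:
            d_up, d_down = midpoint - g.tss, g.tes - midpoint
        if 0 <= d_up <= 1000:
            cat = "promoter"
        elif 1000 < d_up <= 10_000:
            cat = "upstream"
        elif 0 < d_down <= 10_000:
            cat = "downstream"
        elif g.tx_start <= midpoint < g.tx_end:
            cat = "exon" if any(
                e.start <= midpoint < e.end for e in g.exons
            ) else "intron"
        else:
            continue
        if CATEGORIES.index(cat) < CATEGORIES.index(best):
            best = cat
    return best


def random_gene_set(rng, n=50, span=2_000_000):
    genes = []
    starts = np.sort(rng.choice(np.arange(20_000, span, span // n), n, replace=False))
    for k, s in enumerate(starts):
        length = int(rng.integers(2_000, 15_000))
        strand = str(rng.choice(["+", "-"]))
        n_ex = int(rng.integers(1, 5))
        cuts = np.sort(
            rng.choice(np.arange(1, length), 2 * n_ex - 2, replace=False)
        ) if n_ex > 1 else np.array([], int)
        bounds = np.r_[0, cuts, length]
        exons = [
            (int(s + bounds[2 * j]), int(s + bounds[2 * j + 1]))
            for j in range(n_ex)
        ]
        genes.append(
            make_gene(
                tx_start=int(s), tx_end=int(s) + length, strand=strand,
                exons=exons, name=f"G{k}",
            )
        )
    return genes


class TestClassifyPeakLocation:
    def test_promoter_upstream_of_plus_tss(self):
        g = make_gene(tx_start=10_000, tx_end=20_000, strand="+")
        assert classify_peak_location(peak_at(9_500), [g]).category == "promoter"

    def test_exon_hit(self):
        g = make_gene(
            tx_start=10_000, tx_end=20_000,
            exons=[(10_000, 11_000), (15_000, 16_000)],
        )
        assert classify_peak_location(peak_at(15_500), [g]).category == "exon"
        assert classify_peak_location(peak_at(13_000), [g]).category == "intron"

    def test_empty_gene_set_is_intergenic(self):
        assert classify_peak_location(peak_at(1_000), []).category == "intergenic"

    def test_matches_brute_force_and_partitions(self, rng):
        genes = random_gene_set(rng, 50)
        mids = rng.integers(0, 2_000_000, 500)
        counts = dict.fromkeys(CATEGORIES, 0)
        for mid in mids:
            ann = classify_peak_location(peak_at(int(mid)), genes)
            assert ann.category == brute_force_category(int(mid), genes)
            counts[ann.category] += 1
        assert sum(counts.values()) == 500

    def test_strand_flip_mirrors_up_and_downstream(self):
        g_plus = make_gene(tx_start=10_000, tx_end=20_000, strand="+")
        g_minus = make_gene(tx_start=10_000, tx_end=20_000, strand="-")
        # 5 kb left of the gene: upstream for '+', downstream for '-'
        assert classify_peak_location(peak_at(5_000), [g_plus]).category == "upstream"
        assert classify_peak_location(peak_at(5_000), [g_minus]).category == "downstream"
        assert classify_peak_location(peak_at(25_000), [g_plus]).category == "downstream"
        assert classify_peak_location(peak_at(25_000), [g_minus]).category == "upstream"


def expr(tid, tss, ne, chrom="chr1"):
    return ExpressionRecord(
        transcript_id=tid, chrom=chrom, tss=tss,
        raw_read_bp_count=ne * 100 if ne else 0.0, ne=ne,
    )


class TestNearestTranscriptFc:
    def test_tie_breaks_to_lower_coordinate(self):
        a = [expr("T1", 9_000, 1.0), expr("T2", 11_000, 1.0)]
        b = [expr("T1", 9_000, 2.0), expr("T2", 11_000, 4.0)]
        tid, _ = nearest_transcript_fc(peak_at(10_000), a, b)
        assert tid == "T1"

    def test_single_transcript_always_assigned(self):
        a = [expr("T1", 500_000, 1.0)]
        b = [expr("T1", 500_000, 4.0)]
        tid, fc = nearest_transcript_fc(peak_at(10_000), a, b)
        assert tid == "T1"
        assert fc == pytest.approx(np.log2(4.01 / 1.01))

    def test_no_transcript_on_chromosome(self):
        a = [expr("T1", 500, 1.0, chrom="chr9")]
        tid, fc = nearest_transcript_fc(peak_at(10_000), a, a)
        assert tid is None and np.isnan(fc)

    def test_matches_exhaustive_search(self, rng):
        tss = rng.integers(0, 1_000_000, 200)
        a = [expr(f"T{k}", int(t), float(rng.lognormal())) for k, t in enumerate(tss)]
        b = [
            expr(f"T{k}", int(t), float(rng.lognormal()))
            for k, t in enumerate(tss)
        ]
        for mid in rng.integers(0, 1_000_000, 100):
            tid, _ = nearest_transcript_fc(peak_at(int(mid)), a, b)
            dists = [(abs(int(t) - int(mid)), int(t), f"T{k}")
                     for k, t in enumerate(tss)]
            assert tid == min(dists)[2]


class TestEnhancerOverlap:
    def test_flank_boundary(self):
        # peak covers bases 10_000..10_399; a midpoint 999 bp past the end
        # coordinate hits, 1000 bp does not
        peak = GenomicInterval("chr1", 10_000, 10_400)
        near = GenomicInterval("chr1", 11_300, 11_498)  # midpoint 11_399
        far = GenomicInterval("chr1", 11_300, 11_500)   # midpoint 11_400
        hits, enh = enhancer_overlap([peak], [near], flank=1000)
        assert hits and enh
        hits, _ = enhancer_overlap([peak], [far], flank=1000)
        assert not hits

    def test_disjoint_chromosomes_empty(self):
        peak = GenomicInterval("chr1", 0, 100)
        enh = GenomicInterval("chr2", 0, 100)
        assert enhancer_overlap([peak], [enh]) == ([], [])

    def test_matches_all_pairs_oracle(self, rng):
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 400)
            for s in rng.integers(0, 5_000_000, 1000)
        ]
        enhancers = [
            GenomicInterval("chr1", int(s), int(s) + 300)
            for s in rng.integers(0, 5_000_000, 1000)
        ]
        hits, enh_hit = enhancer_overlap(peaks, enhancers, flank=1000)
        expected_hits = []
        expected_enh = set()
        for p in peaks:
            any_hit = False
            for e in enhancers:
                m = e.midpoint
                if p.start - 1000 <= m <= p.end - 1 + 1000:
                    any_hit = True
                    expected_enh.add((e.chrom, e.start, e.end))
            if any_hit:
                expected_hits.append(p)
        assert len(hits) == len(expected_hits)
        assert {(e.chrom, e.start, e.end) for e in enh_hit} == expected_enh


class TestFisherEnrichment:
    def flags(self, a, b, c, d):
        bound = [True] * (a + b) + [False] * (c + d)
        expressed = [True] * a + [False] * b + [True] * c + [False] * d
        return bound, expressed

    def test_no_association(self):
        res = fisher_enrichment(*self.flags(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_perfect_association_hypergeometric_value(self):
        res = fisher_enrichment(*self.flags(5, 0, 0, 5))
        # two-sided: both extreme tables, each 1/C(10,5)
        assert res.p == pytest.approx(2 / 252)

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(0, 12, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            res = fisher_enrichment(*self.flags(a, b, c, d))
            # enumerate all tables with the same margins
            n = a + b + c + d
            row1, col1 = a + b, a + c
            lo = max(0, row1 + col1 - n)
            hi = min(row1, col1)
            probs = {
                x: stats.hypergeom.pmf(x, n, row1, col1)
                for x in range(lo, hi + 1)
            }
            cutoff = probs[a] * (1 + 1e-9)
            expected = sum(v for v in probs.values() if v <= cutoff)
            assert res.p == pytest.approx(expected, rel=1e-6)

    def test_symmetry_under_row_and_column_swap(self):
        res1 = fisher_enrichment(*self.flags(8, 2, 3, 7))
        res2 = fisher_enrichment(*self.flags(7, 3, 2, 8))
        assert res1.p == pytest.approx(res2.p)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            fisher_enrichment([], [])


class TestNormalizeExpression:
    def test_quoted_formula_spot_value(self):
        assert normalize_expression(10, 1e6, 1000) == pytest.approx(0.1)

    def test_zero_reads_give_zero(self):
        assert normalize_expression(0, 1e6, 1000) == 0.0

    def test_invariant_to_joint_doubling(self):
        v1 = normalize_expression(10, 1e6, 1000)
        v2 = normalize_expression(20, 2e6, 1000)
        assert v1 == pytest.approx(v2)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            normalize_expression(10, 1e6, 0)
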