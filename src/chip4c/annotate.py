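"""Relating peaks to genes and enhancers.

Peaks are classified into six genomic categories by their midpoint with
strand-aware distance rules (promoter: within 1 kb upstream of a TSS;
upstream: 1-10 kb upstream; downstream: up to 10 kb past the transcript
end; exon; intron; intergenic otherwise), assigned the nearest transcript
by TSS distance together with its expression fold change, and tested for
enrichment of enhancer overlap with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, GenomicInterval

__all__ = [
    "PeakAnnotation",
    "EnrichmentResult",
    "CATEGORIES",
    "classify_peak_location",
    "nearest_transcript_fc",
    "enhancer_overlap",
    "fisher_enrichment",
    "normalize_expression",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "upstream", "downstream", "exon", "intron", "intergenic")


@dataclass
class PeakAnnotation:
    peak: GenomicInterval
    category: str
    gene: str | None = None


@dataclass
class EnrichmentResult:
    table: tuple  # ((a, b), (c, d)) counts
    odds_ratio: float
    p: float


def _category_for_gene(midpoint: int, gene: GeneModel) -> str | None:
    """Category of a peak midpoint with respect to one gene, or None."""
    if gene.strand == "+":
        d_up = gene.tss - midpoint  # positive when upstream of TSS
        d_down = midpoint - gene.tes  # positive when past the gene end
    else:
        d_up = midpoint - gene.tss
        d_down = gene.tes - midpoint
    if 0 <= d_up <= 1000:
        return "promoter"
    if 1000 < d_up <= 10000:
        return "upstream"
    if 0 < d_down <= 10000:
        return "downstream"
    if gene.tx_start <= midpoint < gene.tx_end:
        for ex in gene.exons:
            if ex.start <= midpoint < ex.end:
                return "exon"
        return "intron"
    return None


def classify_peak_location(peak: GenomicInterval, genes) -> PeakAnnotation:
    """Assign a peak to exactly one genomic category.

    The peak midpoint is placed against every gene on its chromosome and
    the highest-precedence applicable category wins (promoter > upstream
    > downstream > exon > intron); a peak farther than 10 kb from every
    TSS and gene end and outside every gene body is intergenic. Among
    genes yielding the winning category, the one whose TSS is closest is
    reported.
    """
    genes = list(genes)
    if not genes:
        logger.warning("empty gene set: classifying all peaks as intergenic")
        return PeakAnnotation(peak=peak, category="intergenic", gene=None)
    mid = peak.midpoint
    best_rank = len(CATEGORIES) - 1  # intergenic
    best_gene = None
    best_dist = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        cat = _category_for_gene(mid, g)
        if cat is None:
            continue
        rank = CATEGORIES.index(cat)
        dist = abs(g.tss - mid)
        if rank < best_rank or (
            rank == best_rank and best_dist is not None and dist < best_dist
        ):
            best_rank = rank
            best_gene = g
            best_dist = dist
        elif rank == best_rank and best_gene is None:
            best_gene = g
            best_dist = dist
    return PeakAnnotation(
        peak=peak,
        category=CATEGORIES[best_rank],
        gene=best_gene.gene_name if best_gene is not None else None,
    )


def nearest_transcript_fc(
    peak: GenomicInterval,
    expression_a,
    expression_b,
    pseudocount: float = 0.01,
):
    """Nearest transcript by TSS distance, with its expression fold change.

    ``expression_a`` / ``expression_b`` are same-ordered lists of
    :class:`~chip4c.io.ExpressionRecord` for the two conditions. Returns
    ``(transcript_id, log2((NE_b + eps) / (NE_a + eps)))``; ties in
    distance break toward the lower TSS coordinate. Returns
    ``(None, nan)`` when the peak's chromosome carries no transcript.
    """
    center = peak.midpoint
    best = None
    best_key = None
    for rec_a, rec_b in zip(expression_a, expression_b):
        if rec_a.transcript_id != rec_b.transcript_id:
            raise ValueError("expression tables must be ordered identically")
        if rec_a.chrom != peak.chrom:
            continue
        key = (abs(rec_a.tss - center), rec_a.tss)
        if best_key is None or key < best_key:
            best_key = key
            best = (rec_a, rec_b)
    if best is None:
        logger.info("no transcript on %s for peak %s", peak.chrom, peak)
        return None, float("nan")
    rec_a, rec_b = best
    fc = float(
        np.log2((rec_b.ne + pseudocount) / (rec_a.ne + pseudocount))
    )
    return rec_a.transcript_id, fc


def enhancer_overlap(peaks, enhancers, flank: int = 1000):
    """Peaks within +-flank of an enhancer midpoint.

    Returns ``(overlapping_peaks, hit_enhancers)``: the peaks whose
    interval overlaps at least one enhancer midpoint +- flank window, and
    the enhancers hit by at least one peak. A peak may hit several
    enhancers and vice versa.
    """
    peaks = list(peaks)
    enhancers = list(enhancers)
    by_chrom: dict[str, list] = {}
    for e in enhancers:
        by_chrom.setdefault(e.chrom, []).append(e)
    mids = {
        chrom: np.array(sorted(e.midpoint for e in es))
        for chrom, es in by_chrom.items()
    }
    hit_peaks = []
    hit_enh = set()
    for p in peaks:
        arr = mids.get(p.chrom)
        if arr is None:
            continue
        # enhancer midpoint m hits iff [m-flank, m+flank+1) overlaps peak
        lo = np.searchsorted(arr, p.start - flank, side="left")
        hi = np.searchsorted(arr, p.end + flank - 1, side="right")
        if hi > lo:
            hit_peaks.append(p)
            window_lo, window_hi = arr[lo], arr[hi - 1]
            for e in by_chrom[p.chrom]:
                if window_lo <= e.midpoint <= window_hi and (
                    p.start - flank <= e.midpoint <= p.end + flank - 1
                ):
                    hit_enh.add((e.chrom, e.start, e.end))
    hit_enhancers = [
        e for e in enhancers if (e.chrom, e.start, e.end) in hit_enh
    ]
    if peaks and enhancers and not hit_peaks:
        logger.warning(
            "no peak-enhancer overlap at all; check chromosome naming"
        )
    return hit_peaks, hit_enhancers


def fisher_enrichment(bound_flags, expressed_flags) -> EnrichmentResult:
    """Fisher's exact test of association between two enhancer labels.

    ``bound_flags`` and ``expressed_flags`` are boolean vectors over the
    same enhancer universe (e.g. peak-bound x eRNA-expressed). The 2x2
    table is tested two-sided via the hypergeometric distribution; the
    odds ratio uses a Haldane 0.5 correction when any cell is zero.
    """
    bound = np.asarray(bound_flags, dtype=bool)
    expr = np.asarray(expressed_flags, dtype=bool)
    if bound.shape != expr.shape:
        raise ValueError("flag vectors must align")
    if bound.size == 0:
        raise ValueError("enhancer universe is empty")
    a = int((bound & expr).sum())
    b = int((bound & ~expr).sum())
    c = int((~bound & expr).sum())
    d = int((~bound & ~expr).sum())
    table = np.array([[a, b], [c, d]])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if (table == 0).any():
        t = table + 0.5
        odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    else:
        odds = float(a * d / (b * c))
    return EnrichmentResult(table=((a, b), (c, d)), odds_ratio=odds, p=p)


def normalize_expression(
    transcript_reads_bp: float,
    total_mapped_bp: float,
    length_bp: float,
    c: float = 1e7,
) -> float:
    """Normalized expression: NE = c * reads_bp / (total_bp * length_bp).

    ``transcript_reads_bp`` is the base pairs of reads falling in the
    transcript, ``total_mapped_bp`` all mapped base pairs, ``length_bp``
    the transcript length, and ``c`` a constant fixed at 1e7.
    """
    if total_mapped_bp <= 0:
        raise ValueError("total mapped base pairs must be positive")
    if length_bp <= 0:
        raise ValueError("transcript length must be positive")
    if transcript_reads_bp < 0:
        raise ValueError("read count must be non-negative")
    return c * transcript_reads_bp / (total_mapped_bp * length_bp)


def annotate_peaks_frame(peaks, genes, expression_a=None, expression_b=None):
    """Annotated-peak table: category, gene, nearest transcript, log2 fc."""
    rows = []
    for i, p in enumerate(peaks):
        ann = classify_peak_location(p, genes)
        row = {
            "peak_id": f"peak_{i + 1}",
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "category": ann.category,
            "gene": ann.gene,
        }
        if expression_a is not None and expression_b is not None:
            tid, fc = nearest_transcript_fc(p, expression_a, expression_b)
            row["nearest_transcript"] = tid
            row["expression_log2_fc"] = fc
        rows.append(row)
    return pd.DataFrame(rows)
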