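"""Annotate peaks against genes, expression and enhancers.

Simulates a gene annotation with planted expression fold changes, places
peaks, classifies each into a genomic category, assigns the nearest
transcript's expression change, and tests enhancer-overlap enrichment
with Fisher's exact test.
"""

import numpy as np

from chip4c import (
    GenomicInterval,
    classify_peak_location,
    enhancer_overlap,
    fisher_enrichment,
    nearest_transcript_fc,
    simulate_annotation_and_expression,
)
from chip4c.annotate import CATEGORIES

GENOME = [("chr1", 5_000_000)]
rng = np.random.default_rng(0)

genes, expr_a, expr_b, truth = simulate_annotation_and_expression(
    50, GENOME, seed=0
)
peaks = [
    GenomicInterval("chr1", int(s), int(s) + 400)
    for s in rng.integers(0, 4_999_000, 200)
]

counts = dict.fromkeys(CATEGORIES, 0)
for p in peaks:
    counts[classify_peak_location(p, genes).category] += 1
print("genomic categories of 200 peaks:", counts)

tid, fc = nearest_transcript_fc(peaks[0], expr_a, expr_b)
print(f"peak 1 nearest transcript: {tid}, expression log2 fc {fc:+.2f}")

# enhancers placed on top of the first 30 peaks: strong overlap enrichment
enhancers = [
    GenomicInterval("chr1", p.midpoint - 150, p.midpoint + 150)
    for p in peaks[:30]
] + [
    GenomicInterval("chr1", int(s), int(s) + 300)
    for s in rng.integers(0, 4_999_000, 170)
]
hit_peaks, hit_enh = enhancer_overlap(peaks, enhancers, flank=1000)
print(f"{len(hit_peaks)}/200 peaks within 1 kb of an enhancer midpoint "
      f"({len(hit_enh)} enhancers hit)")

hit_keys = {(e.chrom, e.start, e.end) for e in hit_enh}
bound = np.array([(e.chrom, e.start, e.end) in hit_keys for e in enhancers])
expressed = np.r_[np.ones(30, bool), rng.random(170) < 0.2]
res = fisher_enrichment(bound, expressed)
print(f"bound x expressed 2x2 table {res.table}: "
      f"odds ratio {res.odds_ratio:.1f}, Fisher p = {res.p:.2e}")
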