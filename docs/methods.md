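# Methods

This note documents the models and procedures chip4c implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the places where the design was genuinely open.

## Coordinates and formats

All coordinates are 0-based half-open (BED-native) everywhere inside the
package; conversion would happen only at format boundaries (refFlat
txStart is already 0-based, so the reader does none). Chromosome names
are taken verbatim; mismatched naming between inputs surfaces as an
empty-overlap warning rather than silent renaming.

## ChIP signal model

A sequencing read represents one end of an immunoprecipitated DNA
fragment. The pipeline therefore (1) keeps one read per (chromosome, 5′
position, strand) — colliding reads are overwhelmingly PCR duplicates at
ChIP depths; (2) extends each read from its 5′ end to the library's
fragment size (default 300 bp, a config input rather than an estimated
quantity); (3) counts, for a region, the extended fragments overlapping
it by ≥ 1 bp. Whole-fragment overlap counting (rather than midpoint or
partial-weight counting) was chosen because the quantification unit is
"fragments overlapping an area"; the choice matters only at region
borders, at the scale of one fragment size.

Signal is expressed in fragments per million reads per kbp:

    signal = (count / (1 + L/b)) / (library_size/10^6) / (region_bp/1000)

where L is the fragment size and b the bin size (default 100 bp). The
divisor 1 + L/b converts bin-overlap events back to fragment units: an
L-bp fragment overlaps that many consecutive b-bp bins on average.

Quantile normalization equalizes sample distributions before
between-sample comparisons (ChIP efficiency varies between libraries).
Each column's order statistics are replaced by the across-column mean of
order statistics; ties receive the mean of the order-statistic means
they span (mid-rank convention), which makes the operation deterministic,
symmetric in tied entries, and idempotent. A consequence worth knowing:
with heavy ties (integer counts), the sorted values of two normalized
columns agree only up to tie-group averaging, not exactly.

## Peak calling

The caller is a window scanner with locally adaptive Poisson thresholds.

*NCIS background scaling.* Control and sample depths differ, and the
control has no enriched fraction; scaling by total library size would
therefore overestimate the control's background. Following the
low-signal-bin idea of NCIS, genome-wide window-size bins are ordered by
total (sample + control) count; r(t) = Σsample/Σcontrol over bins with
total ≤ t is tracked over increasing t and accepted at the smallest t
where it changes < 1% relative to the previous distinct total and ≥ 75%
of bins are included. The stopping rule is fixed for determinism; on
pure-scaling fixtures it recovers the depth ratio to well under 1%, and
a small enriched bin fraction does not move it (both covered by tests).
A 0.5 pseudocount guards the degenerate all-zero cumulative case; an
entirely empty control is an error.

*Thresholds.* The global threshold is the smallest count k with
P(X ≥ k | λ) ≤ 10⁻⁵ for λ = the genome-wide mean extended-fragment
count per 100-bp window of the sample. Local thresholds use λ = r ×
mean control count per window over 1 kb, 5 kb and 25 kb spans centered
on the window. Because the threshold is non-decreasing in λ, the "most
conservative threshold" (maximum over the four) equals the threshold at
the maximum λ; that λ is also used for the window's p-value. Thresholds
are always computed on raw integer counts; the ε = 0.5 pseudocount
appears only inside fold ratios.

*Window filters.* A window from any of the four shifted tilings (shift
25 bp, 4 passes covering one window size) is a candidate when its count
reaches its most conservative threshold, log₂((count+ε)/(r·control+ε))
> 2, and its extended-fragment signal is strand-balanced (max/min < 3,
both strands non-zero). Extended-fragment signal is used at the window
level because a genuine crosslink pileup covers its summit from both
strands, whereas the window's raw 5′ reads can legitimately be
one-sided at the summit flanks.

*Assembly.* Candidates from all passes are unioned, then merged
transitively (overlap or gap ≤ 100 bp). Each merged region's borders are
refined by sliding a 100-bp window at 1-bp resolution over ± one window
size around each temporary border, moving outward from the interior; the
first position where the count falls below the region's threshold
becomes the new border (unchanged if it never falls below in range).
Flanks whose centered window count is below µ + 2·SD — estimated from
the genome-wide distribution of window counts excluding candidate
windows, i.e. the background distribution — are then trimmed; a peak
emptied by refinement is dropped with a logged reason. The summit is the
1-bp position maximizing the centered window count (leftmost on ties).

*Peak statistics and selection.* A peak inherits its windows'
statistics: the minimum Poisson p over constituent windows and the
maximum window-level NCIS fold (a region-wide average would dilute a
narrow summit with its refined flanks). A second strand-balance check is
applied at the peak level on un-extended 5′ read positions inside the
refined interval — both 5′ clusters of a real pileup lie within it,
while one-strand artifacts fail. Benjamini–Hochberg q-values are
computed over all scanned windows' p-values (the hypotheses actually
tested, ~4 per 100 bp of genome); a peak is kept iff its best window's
q ≤ 10⁻⁵ and its fold ≥ 2. The optional cross-condition exclusion
removes peaks whose signal in another library exceeds 0.76
fragments/kbp/M (strictly) within ± 500 bp of the peak center.

Whether the four shifted passes were unioned before or after merging is
not derivable from the procedure's description; union-then-merge is
implemented (the alternative gives the same merged regions up to border
jitter below one window size).

## Differential marks

`differential_tss` is an explicit, documented stand-in for a
shrinkage-based NB framework, kept behind a stable contract so it could
be swapped out. Size factors are median-of-ratios against the row-wise
geometric mean. Dispersion is a single pooled α from the method-of-
moments identity Var = µ + αµ² — estimated as
Σ(var_i − µ_i) / Σµ_i² across rows, a ratio of sums: per-row variance
estimates at 1–2 degrees of freedom are far too noisy to use
individually, and the median of per-row ratios is biased low, while the
ratio of sums is consistent. The Wald statistic divides the log₂ fold
change (ε = 0.5 on normalized means) by the delta-method standard error
√((1/µ_A + α)/n_A + (1/µ_B + α)/n_B)/ln 2 against a normal reference.
Omitted relative to full frameworks: dispersion shrinkage toward a mean
trend, outlier refitting, LFC moderation. With the count filters in
front (≥ 15 per sample, ≥ 100 total), rows are well-measured and the
simple test is calibrated: type-I error at nominal 0.05 lands near
0.046–0.067 across seeds on NB nulls with dispersion 0.1 at two
replicates per condition.

One property of median-of-ratios normalization matters for validation
design: a fold change planted in *every* row is indistinguishable from a
depth difference and is absorbed by the size factors (any such method,
including DESeq2, does this). Recovery benchmarks therefore plant
effects in a subset of rows, symmetrically up and down so the size
factors stay neutral.

Two-fold classification operates on quantile-normalized continuous
signal: regions below a mark-specific floor in both samples (0.5 for
H3K27me3, 5 for H3K4me3 signal units) are set aside as unclassifiable;
otherwise gain is log₂(b/a) ≥ 1 and loss ≤ −1. The peak-level mark
classifier uses the same ± 1 cutoffs on log₂((day10+0.5)/(day0+0.5))
and partitions every peak set exhaustively. The loss cutoff is −1 by
symmetry with gain (+1).

## 4C differential contacts

The quantification unit is the restriction fragment end, indexed along
the chromosome; each fragment end's signal sits at its fragment's center
coordinate, and all windows are defined in fragment-end units (21 ends),
not base pairs. The viewpoint end and its two immediate neighbours (the
non-cut and self-ligation products) are discarded. Blind fragment ends
(no secondary restriction site) have systematically different count
statistics, so blind and non-blind ends are quantile-normalized between
the two conditions separately; profiles are then scaled to reads per
million. Quantile normalization is scale-destroying, so it precedes the
library-size scaling. Smoothing uses a 10% trimmed mean (drop
floor(0.1·n) values per tail — the central 17 of 21) with proportional
re-trimming at profile edges.

The differential test is rank-based, which makes it insensitive to
PCR-amplification outliers and invariant to monotone transformations of
the normalized values. Within each 21-end window the 42 values of both
conditions are pooled and mid-ranked; with O_A the rank sum of condition
A, E = n_A(N+1)/2 its null expectation and
Var = n_A n_B/12 · ((N+1) − Σ(t³−t)/(N(N−1))) the exact tie-corrected
rank-sum variance, the statistic χ² = (O_A − E)²/Var is referred to a
χ² distribution with 1 df (the squared normal approximation of the
two-sample rank-sum test; all-ties windows get χ² = 0, p = 1). This
construction was chosen over two alternatives after checking their
operating characteristics: normalizing by E instead of Var is badly
anti-conservative (its null expectation is ≈ 7, not 1), while ranking
the two conditions per fragment end (ranks in {1, 2}) caps the
statistic at 7.0 (p = 0.008), which no BH threshold below 0.01 can ever
select. The implemented statistic is calibrated under exchangeable
nulls (checked against a permutation oracle and by simulation) and
recovers planted 10× contact blocks of ≥ 30 ends essentially always.
Windows at BH q < 0.01 are grouped into maximal runs of consecutive
significant windows with the same winner (the condition with the higher
trimmed mean) and reported as contact regions — regions, not single
windows, are the natural reporting unit for a contact spanning many
fragment ends.

A caveat inherited from between-condition quantile normalization: in
the viewpoint-proximal zone both conditions occupy the top tail of
their distributions, and rank-preserving normalization there leaves
little room for a differential signal to express itself. Benchmarks
therefore plant contacts at regulatory-loop distance (several hundred
kb from the viewpoint), where real differential looping is sought.

## Annotation

Peak classification uses the peak midpoint (a deterministic anchor) and
strand-aware distances: promoter = within 1 kb upstream of a TSS,
upstream = 1–10 kb upstream, downstream = up to 10 kb past the
transcript end, then exon, then intron, intergenic otherwise. The
precedence order follows the category list; it is applied across all
genes on the chromosome (a promoter hit with respect to any gene beats
an intron hit), and among genes giving the winning category the closest
TSS is reported. The labels always partition the peak set. Nearest-
transcript assignment minimizes TSS distance to the peak midpoint with
ties broken toward the lower coordinate; the expression fold change is
log₂((NE_B+ε)/(NE_A+ε)) with ε = 0.01, a small constant relative to
typical NE values (NE = 10⁷·reads_bp/(total_bp·length_bp), so order
0.1–1). Enhancer overlap asks whether the peak interval intersects the
enhancer midpoint ± 1 kb; Fisher's exact test on the bound × expressed
2×2 table is two-sided (no directionality assumed), with a Haldane 0.5
correction for the odds ratio when a cell is zero.

## Synthetic data: what it does and does not emulate

`simulate_chip` draws background read 5′ positions from a homogeneous
Poisson process split evenly between strands; a planted peak of width w
and fold f adds (f−1)·rate·w expected reads with plus-strand 5′ ends
offset −shift/2 and minus-strand +shift/2 from the peak span (shift
defaults to the fragment size, giving the bimodal pattern the strand
filter expects; shift 0 with `single_strand=True` creates the
amplification-artifact geometry the filter must reject). The control is
background-only at 0.7× the sample depth by default — an IgG-like
library at its own depth. The default benchmark genome is 10 Mb at
1M reads, reproducing the per-window background density (λ ≈ 40
fragments/100 bp) of a deeply sequenced mammalian library at desktop
runtime; peaks are 400 bp at 10× enrichment, 50 per genome.

`simulate_fourc` draws negative-binomial counts (size 5 by default —
Poisson is unrealistically calm for 4C) around a monotone decay
A/(1+d/d₀)^α of the distance d from the viewpoint; planted contacts
multiply one condition's mean over a block of fragment ends. Blind
flags are independent of signal at a 30% fraction.

Not emulated, hence not demonstrated by passing tests: sequence content
and mappability/GC bias, duplicate-rate structure beyond position
collisions, replicate correlation beyond shared means, trans-chromosomal
4C signal, and biological covariation between marks. Results on real
libraries additionally depend on alignment quality, which is outside
this package's scope (reads enter as aligned intervals).

## Numerical choices and degenerate inputs

Poisson thresholds: smallest integer k with sf(k−1, λ) ≤ p, computed
via the inverse survival function plus an exact local adjustment; λ = 0
gives k = 1. BH is statsmodels' step-up (an independent hand-written
implementation serves as the test oracle). Fisher p-values come from the
conditional hypergeometric two-sided rule. All simulation entry points
take a single integer seed and are bit-reproducible; the pipeline
orchestrator stamps outputs with the package version, a hash of the
analysis-relevant config (output paths excluded) and the seed. Empty
libraries, zero-length regions, all-zero controls, unknown viewpoints,
mismatched fragment maps and non-integer count matrices all raise with
specific messages rather than propagating NaNs.

## Benchmark problem sizes

The default benchmark sizes — 10 Mb / 1M reads / 50 peaks for recovery,
20 seeded background-only runs for the null, 5 000 fragment ends and 20
seeds per 4C condition, 5 000-row NB nulls, 500-row planted effects, and
≥ 1 000 instances per brute-force oracle — were chosen as the smallest
scales at which the measured rates are stable to well under the margins
asserted in the acceptance tests.
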