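"""Window-based ChIP-seq peak calling with NCIS-scaled Poisson thresholds.

The caller scans the genome in 100-bp windows, four times with the tiling
shifted 25 bp each pass. A window becomes a candidate when its extended-
fragment count reaches the most conservative of four Poisson thresholds
(global sample background, plus control background over 10x/50x/250x
window spans scaled by the NCIS factor), its NCIS-normalized log2
sample/control fold exceeds 2, and its plus/minus 5'-read signal is
balanced within 3:1. Candidates from all passes are unioned, merged
(gap <= 100 bp), border-refined at 1-bp resolution, shoulder-trimmed at
mu + 2 SD of the background window distribution, and finally selected at
a Benjamini-Hochberg FDR of 1e-5 over all tested windows with a minimum
NCIS-normalized log2 fold of 2. An optional post-filter removes peaks
whose signal in a second condition exceeds a fixed fragments/kbp/M cap.

The NCIS factor r rescales control counts to the sample's background
depth. It is estimated from window bins ordered by total (sample+control)
count: r(t) is the cumulative sample/control ratio over bins with total
<= t, and r is read off at the smallest t where r(t) has stabilized
(relative change < 1%) and at least 75% of bins are included — low-total
bins are background-dominated, so the ratio there reflects background
depth rather than enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval
from .signal import ReadSet, deduplicate, extend_reads, quantify_region

__all__ = [
    "PeakCallingParams",
    "NcisFactor",
    "CandidateWindow",
    "Peak",
    "PeakSet",
    "estimate_ncis",
    "poisson_threshold",
    "local_thresholds",
    "scan_windows",
    "strand_filter",
    "merge_windows",
    "refine_borders",
    "fdr_select",
    "exclude_by_other_condition",
    "call_peaks",
]

logger = logging.getLogger(__name__)


@dataclass
class PeakCallingParams:
    """Tuning constants of the window peak caller (defaults are canonical)."""

    window_size: int = 100
    shift_step: int = 25
    n_passes: int = 4
    p_threshold: float = 1e-5
    local_scales: tuple = (10, 50, 250)
    min_log2_fold: float = 2.0
    strand_ratio_max: float = 3.0
    merge_gap: int = 100
    shoulder_sd_mult: float = 2.0
    fdr_threshold: float = 1e-5
    fragment_size: int = 300
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "window_size", "shift_step", "n_passes", "p_threshold",
            "min_log2_fold", "strand_ratio_max", "merge_gap",
            "shoulder_sd_mult", "fdr_threshold", "fragment_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_passes * self.shift_step != self.window_size:
            raise ValueError("n_passes * shift_step must equal window_size")


@dataclass
class NcisFactor:
    """Control-to-sample background scaling factor."""

    r: float
    bins_used: int
    background_fraction: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("NCIS factor must be positive")


@dataclass
class CandidateWindow:
    interval: GenomicInterval
    sample_count: int
    control_count: int
    lambda_used: float
    poisson_p: float
    log2_fold_ncis: float
    threshold: int
    plus_count: int = 0
    minus_count: int = 0


@dataclass
class Peak:
    interval: GenomicInterval
    summit: int
    best_p: float
    q_value: float
    log2_fold_ncis: float
    plus_count: int
    minus_count: int
    lambda_used: float = 0.0
    n_windows: int = 0

    @property
    def name(self) -> str:
        return f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"


@dataclass
class PeakSet:
    peaks: list
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.peaks):
            q = max(p.q_value, 1e-300)
            rows.append(
                {
                    "chrom": p.interval.chrom,
                    "start": p.interval.start,
                    "end": p.interval.end,
                    "name": f"peak_{i + 1}",
                    "score": round(-10.0 * math.log10(q), 2),
                    "strand": ".",
                    "best_p": p.best_p,
                    "q_value": p.q_value,
                    "log2_fold": p.log2_fold_ncis,
                    "summit_offset": p.summit - p.interval.start,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "start", "end", "name", "score", "strand",
                "best_p", "q_value", "log2_fold", "summit_offset",
            ],
        )

    def write_bed(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(header.rstrip("\n") + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, header=False)


def estimate_ncis(sample_bins, control_bins) -> NcisFactor:
    """Estimate the NCIS background scaling factor from binned counts.

    Bins are ordered by total (sample + control) count; the cumulative
    sample/control ratio r(t) over bins with total <= t is tracked across
    increasing t and accepted at the smallest t where it changes by less
    than 1% relative to the previous t and at least 75% of bins are
    covered. Falls back to a 0.5 pseudocount if the cumulative control
    count is zero at the stopping point.
    """
    s = np.asarray(sample_bins, dtype=np.int64)
    c = np.asarray(control_bins, dtype=np.int64)
    if s.shape != c.shape:
        raise ValueError("sample and control bin vectors must align")
    if c.sum() == 0:
        raise ValueError("control library empty")
    total = s + c
    order = np.argsort(total, kind="mergesort")
    s_sorted, c_sorted, t_sorted = s[order], c[order], total[order]
    # cumulative sums at the last bin of each distinct total value
    distinct, last_idx = np.unique(t_sorted, return_index=True)
    last_idx = np.r_[last_idx[1:] - 1, len(t_sorted) - 1]
    cum_s = np.cumsum(s_sorted)[last_idx]
    cum_c = np.cumsum(c_sorted)[last_idx]
    cum_n = last_idx + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        r_t = np.where(cum_c > 0, cum_s / np.maximum(cum_c, 1), np.inf)
    n_bins = len(s)
    chosen = len(distinct) - 1
    for i in range(1, len(distinct)):
        if r_t[i - 1] > 0 and np.isfinite(r_t[i - 1]):
            rel = abs(r_t[i] - r_t[i - 1]) / r_t[i - 1]
        else:
            rel = np.inf
        if rel < 0.01 and cum_n[i] >= 0.75 * n_bins:
            chosen = i
            break
    if cum_c[chosen] == 0 or cum_s[chosen] == 0:
        r = (cum_s[chosen] + 0.5) / (cum_c[chosen] + 0.5)
    else:
        r = cum_s[chosen] / cum_c[chosen]
    return NcisFactor(
        r=float(r),
        bins_used=int(cum_n[chosen]),
        background_fraction=float(cum_n[chosen] / n_bins),
    )


def poisson_threshold(lam: float, p: float) -> int:
    """Smallest integer count k with P(X >= k | lam) <= p."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if lam == 0:
        return 1
    k = int(stats.poisson.isf(p, lam)) + 1
    while stats.poisson.sf(k - 1, lam) > p:
        k += 1
    while k > 1 and stats.poisson.sf(k - 2, lam) <= p:
        k -= 1
    return k


def _poisson_threshold_vec(lam: np.ndarray, p: float) -> np.ndarray:
    """Vectorized poisson_threshold (same contract, array lambda)."""
    lam = np.asarray(lam, dtype=float)
    k = np.where(lam > 0, stats.poisson.isf(p, np.maximum(lam, 1e-300)), 0.0)
    k = k.astype(np.int64) + 1
    for _ in range(64):  # isf is off by at most a step or two
        too_low = stats.poisson.sf(k - 1, lam) > p
        if not too_low.any():
            break
        k[too_low] += 1
    for _ in range(64):
        can_drop = (k > 1) & (stats.poisson.sf(k - 2, lam) <= p)
        if not can_drop.any():
            break
        k[can_drop] -= 1
    return k


def local_thresholds(
    control: ReadSet,
    chrom: str,
    position: int,
    params: PeakCallingParams,
    ncis: NcisFactor,
    global_lambda: float,
) -> int:
    """Most conservative Poisson threshold at one genomic position.

    Takes the maximum over the global sample threshold and thresholds from
    NCIS-scaled mean control counts per window over spans of 10x, 50x and
    250x the window size centered on the position. Poisson thresholds are
    non-decreasing in lambda, so this equals the threshold at the maximum
    lambda.
    """
    w = params.window_size
    lams = [global_lambda]
    for scale in params.local_scales:
        span = scale * w
        lo = max(position - span // 2, 0)
        hi = position + span // 2
        cnt = float(control.count_overlaps(chrom, [lo], [hi])[0])
        lams.append(ncis.r * cnt / scale)
    return poisson_threshold(max(lams), params.p_threshold)


def strand_filter(plus_count, minus_count, strand_ratio_max: float = 3.0) -> bool:
    """True when the strand signal is balanced within the ratio cap.

    Strictly less than the cap passes; any zero strand fails (real
    fragment pileups produce signal on both strands).
    """
    if plus_count < 0 or minus_count < 0:
        raise ValueError("strand counts must be non-negative")
    if plus_count == 0 or minus_count == 0:
        return False
    hi, lo = max(plus_count, minus_count), min(plus_count, minus_count)
    return hi / lo < strand_ratio_max


def _five_prime_counts(readset: ReadSet, chrom, win_starts, win_ends):
    """Per-strand counts of read 5' positions inside each window.

    Works on extended fragments too: a plus fragment keeps its 5' end at
    ``start`` and a minus fragment at ``end - 1``.
    """
    plus_starts, _ = readset.chrom_arrays(chrom, "+")
    _, minus_ends = readset.chrom_arrays(chrom, "-")
    win_starts = np.asarray(win_starts)
    win_ends = np.asarray(win_ends)
    plus = np.searchsorted(plus_starts, win_ends, side="left") - np.searchsorted(
        plus_starts, win_starts, side="left"
    )
    # minus 5' base sits at end-1; end-1 in [s, e) <=> end in [s+1, e+1)
    minus = np.searchsorted(minus_ends, win_ends + 1, side="left") - np.searchsorted(
        minus_ends, win_starts + 1, side="left"
    )
    return plus, minus


def _scan_chrom(sample, control, chrom, length, params, ncis, global_lambda):
    """Scan one chromosome across all shifted tilings.

    Returns (candidate rows, all window p-values, base-tiling counts).
    """
    w = params.window_size
    r = ncis.r
    global_thr = poisson_threshold(global_lambda, params.p_threshold)
    eps = params.pseudocount
    candidates = []
    all_pvals = []
    base_counts = None
    for pass_i in range(params.n_passes):
        shift = pass_i * params.shift_step
        w0 = np.arange(shift, max(length - w + 1, shift + 1), w, dtype=np.int64)
        w1 = w0 + w
        cnt = sample.count_overlaps(chrom, w0, w1)
        if pass_i == 0:
            base_counts = (w0, cnt.copy())
        pvals = stats.poisson.sf(cnt - 1, global_lambda)
        pre = np.flatnonzero(cnt >= global_thr)
        if len(pre):
            centers = w0[pre] + w // 2
            lam = np.full(len(pre), global_lambda)
            for scale in params.local_scales:
                span = scale * w
                lo = np.maximum(centers - span // 2, 0)
                hi = centers + span // 2
                c_span = control.count_overlaps(chrom, lo, hi)
                lam = np.maximum(lam, r * c_span / scale)
            thr = _poisson_threshold_vec(lam, params.p_threshold)
            p_pre = stats.poisson.sf(cnt[pre] - 1, lam)
            pvals[pre] = p_pre
            ctrl_cnt = control.count_overlaps(chrom, w0[pre], w1[pre])
            fold = np.log2((cnt[pre] + eps) / (r * ctrl_cnt + eps))
            # window strand balance on extended-fragment signal: a real
            # crosslink pileup covers its summit from both strands
            plus = sample.count_overlaps(chrom, w0[pre], w1[pre], "+")
            minus = sample.count_overlaps(chrom, w0[pre], w1[pre], "-")
            keep = (
                (cnt[pre] >= thr)
                & (fold > params.min_log2_fold)
                & (plus > 0)
                & (minus > 0)
                & (
                    np.maximum(plus, minus)
                    < params.strand_ratio_max * np.minimum(plus, minus)
                )
            )
            for j in np.flatnonzero(keep):
                i = pre[j]
                candidates.append(
                    CandidateWindow(
                        interval=GenomicInterval(chrom, int(w0[i]), int(w1[i])),
                        sample_count=int(cnt[i]),
                        control_count=int(ctrl_cnt[j]),
                        lambda_used=float(lam[j]),
                        poisson_p=float(p_pre[j]),
                        log2_fold_ncis=float(fold[j]),
                        threshold=int(thr[j]),
                        plus_count=int(plus[j]),
                        minus_count=int(minus[j]),
                    )
                )
        all_pvals.append(pvals)
    return candidates, np.concatenate(all_pvals), base_counts


def scan_windows(sample, control, params, ncis, genome):
    """Candidate windows over all shifted tilings of the genome.

    ``sample`` and ``control`` must be deduplicated, extended read sets;
    ``genome`` is a list of (chrom, length). See the module docstring for
    the three filters each window must pass.
    """
    global_lambda = _global_lambda(sample, genome, params)
    out = []
    for chrom, length in sorted(genome):
        cands, _, _ = _scan_chrom(
            sample, control, chrom, length, params, ncis, global_lambda
        )
        out.extend(cands)
    return out


def _global_lambda(sample: ReadSet, genome, params) -> float:
    """Genome-wide mean extended-fragment count per window (base tiling)."""
    w = params.window_size
    total = 0.0
    n = 0
    for chrom, length in genome:
        w0 = np.arange(0, max(length - w + 1, 1), w, dtype=np.int64)
        cnt = sample.count_overlaps(chrom, w0, w0 + w)
        total += cnt.sum()
        n += len(w0)
    return total / n if n else 0.0


def merge_windows(candidates, merge_gap: int = 100):
    """Merge overlapping or near-adjacent candidate windows into regions.

    Transitive closure of overlap-or-gap<=merge_gap; result is sorted and
    independent of input order.
    """
    intervals = sorted(
        (c.interval if isinstance(c, CandidateWindow) else c) for c in candidates
    )
    merged: list[GenomicInterval] = []
    for iv in intervals:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= merge_gap
        ):
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end, merged[-1].strand
                )
        else:
            merged.append(iv)
    return merged


def _window_counts_at(sample, chrom, positions, w, anchor):
    """Sample counts in 100-bp windows anchored at 1-bp positions.

    anchor='right': window [p, p+w) (used for the left border);
    anchor='left': window [p-w, p) (right border); anchor='center':
    window [p - w//2, p + w - w//2).
    """
    positions = np.asarray(positions, dtype=np.int64)
    if anchor == "right":
        lo, hi = positions, positions + w
    elif anchor == "left":
        lo, hi = positions - w, positions
    else:
        lo, hi = positions - w // 2, positions + (w - w // 2)
    lo = np.maximum(lo, 0)
    hi = np.maximum(hi, lo + 1)
    return sample.count_overlaps(chrom, lo, hi)


def refine_borders(
    interval: GenomicInterval,
    sample: ReadSet,
    threshold: int,
    params: PeakCallingParams,
    background_mu: float = 0.0,
    background_sd: float = 0.0,
):
    """Refine a merged region's borders and trim sub-background shoulders.

    Each border is scanned at 1-bp resolution over +-window_size; moving
    outward from the interior, the first position where the 100-bp window
    count falls below the threshold becomes the new border (unchanged if
    the count never falls below within the scan range). Flanks whose
    centered window count is below mu + shoulder_sd_mult * SD of the
    background window distribution are then trimmed. Returns the refined
    interval, or None when refinement empties the peak.
    """
    w = params.window_size
    chrom = interval.chrom
    # left border: windows [p, p+w), scanned from inside (high p) outward
    ps = np.arange(interval.start + w, max(interval.start - w, 0) - 1, -1)
    cnt = _window_counts_at(sample, chrom, ps, w, "right")
    below = np.flatnonzero(cnt < threshold)
    new_start = int(ps[below[0]]) if len(below) else interval.start
    # right border: windows [p-w, p), scanned from inside outward
    ps = np.arange(interval.end - w, interval.end + w + 1)
    ps = ps[ps >= 1]
    cnt = _window_counts_at(sample, chrom, ps, w, "left")
    below = np.flatnonzero(cnt < threshold)
    new_end = int(ps[below[0]]) if len(below) else interval.end
    if new_end <= new_start:
        logger.info("peak %s emptied by border refinement", interval)
        return None
    # shoulder exclusion at mu + k*SD of the background window counts
    cut = background_mu + params.shoulder_sd_mult * background_sd
    if cut > 0:
        pos = np.arange(new_start, new_end)
        sig = _window_counts_at(sample, chrom, pos, w, "center")
        ok = np.flatnonzero(sig >= cut)
        if len(ok) == 0:
            logger.info("peak %s emptied by shoulder exclusion", interval)
            return None
        new_start, new_end = int(pos[ok[0]]), int(pos[ok[-1]]) + 1
    return GenomicInterval(chrom, new_start, new_end)


def fdr_select(peaks, all_window_pvalues, fdr_threshold: float = 1e-5,
               min_log2_fold: float = 2.0) -> PeakSet:
    """Benjamini-Hochberg selection of peaks over all tested windows.

    q-values are computed across every scanned window's Poisson p-value
    (the hypotheses actually tested); each peak inherits the q of its best
    window and is kept iff q <= fdr_threshold and its NCIS-normalized
    log2 fold is at least min_log2_fold.
    """
    pvals = np.asarray(all_window_pvalues, dtype=float)
    if len(pvals) == 0:
        return PeakSet(peaks=[])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    order = np.argsort(pvals, kind="mergesort")
    sorted_p = pvals[order]
    sorted_q = qvals[order]
    kept = []
    for p in peaks:
        idx = np.searchsorted(sorted_p, p.best_p, side="left")
        idx = min(idx, len(sorted_q) - 1)
        p.q_value = float(max(sorted_q[idx], p.best_p))
        if p.q_value <= fdr_threshold and p.log2_fold_ncis >= min_log2_fold:
            kept.append(p)
    return PeakSet(peaks=kept)


def exclude_by_other_condition(
    peakset: PeakSet,
    other: ReadSet,
    max_signal: float = 0.76,
    flank: int = 500,
) -> PeakSet:
    """Drop peaks already carrying signal in another condition.

    A peak is removed iff the other condition's signal, quantified over
    peak center +- flank in fragments/kbp/M, strictly exceeds max_signal.
    """
    kept = []
    for p in peakset.peaks:
        center = p.interval.midpoint
        region = GenomicInterval(
            p.interval.chrom, max(center - flank, 0), center + flank
        )
        if quantify_region(other, region) <= max_signal:
            kept.append(p)
    diag = dict(peakset.diagnostics)
    diag["excluded_by_other"] = len(peakset.peaks) - len(kept)
    return PeakSet(peaks=kept, diagnostics=diag)


def call_peaks(
    sample_reads: ReadSet,
    control_reads: ReadSet,
    genome,
    params: PeakCallingParams | None = None,
    exclude_in: ReadSet | None = None,
    exclude_max: float = 0.76,
) -> PeakSet:
    """Run the full peak-calling procedure.

    ``sample_reads`` and ``control_reads`` are raw stranded read sets
    (deduplicated here if needed); ``genome`` is a list of
    (chrom, length). Returns the FDR-selected :class:`PeakSet` with
    per-stage diagnostics.
    """
    params = params or PeakCallingParams()
    sample = deduplicate(sample_reads)
    control = deduplicate(control_reads)
    sample_ext = extend_reads(sample, params.fragment_size)
    control_ext = extend_reads(control, params.fragment_size)
    w = params.window_size

    # NCIS from 5'-position counts in window-size bins
    s_bins, c_bins = [], []
    for chrom, length in sorted(genome):
        n_bins = max(length // w, 1)
        for rs, acc in ((sample, s_bins), (control, c_bins)):
            df = rs.reads
            mask = df["chrom"].values == chrom
            five = np.where(
                df["strand"].values[mask] == "-",
                df["end"].values[mask] - 1,
                df["start"].values[mask],
            )
            five = five[(five >= 0) & (five < n_bins * w)]
            acc.append(np.bincount(five // w, minlength=n_bins))
    ncis = estimate_ncis(np.concatenate(s_bins), np.concatenate(c_bins))

    global_lambda = _global_lambda(sample_ext, genome, params)
    global_thr = poisson_threshold(global_lambda, params.p_threshold)

    candidates = []
    pvals_parts = []
    bg_counts_parts = []
    for chrom, length in sorted(genome):
        cands, pvals, (_base_w0, base_cnt) = _scan_chrom(
            sample_ext, control_ext, chrom, length, params, ncis, global_lambda
        )
        candidates.extend(cands)
        pvals_parts.append(pvals)
        # exclude base windows overlapping candidates from the background
        mask = np.ones(len(base_cnt), dtype=bool)
        for c in cands:
            lo = max((c.interval.start - w) // w + 1, 0)
            hi = min(c.interval.end // w + 1, len(base_cnt))
            mask[lo:hi] = False
        bg_counts_parts.append(base_cnt[mask])
    all_pvals = np.concatenate(pvals_parts) if pvals_parts else np.array([])
    bg = (
        np.concatenate(bg_counts_parts)
        if bg_counts_parts
        else np.array([0.0])
    )
    bg_mu = float(bg.mean()) if len(bg) else 0.0
    bg_sd = float(bg.std()) if len(bg) else 0.0

    merged = merge_windows(candidates, params.merge_gap)

    cand_by_chrom: dict[str, list[CandidateWindow]] = {}
    for c in candidates:
        cand_by_chrom.setdefault(c.interval.chrom, []).append(c)

    peaks = []
    for region in merged:
        members = [
            c
            for c in cand_by_chrom.get(region.chrom, [])
            if c.interval.overlaps(region)
        ]
        thr = max(c.threshold for c in members)
        refined = refine_borders(
            region, sample_ext, thr, params, bg_mu, bg_sd
        )
        if refined is None:
            continue
        best = min(members, key=lambda c: c.poisson_p)
        pos = np.arange(refined.start, refined.end)
        sig = _window_counts_at(sample_ext, refined.chrom, pos, w, "center")
        summit = int(pos[int(np.argmax(sig))])
        plus, minus = _five_prime_counts(
            sample_ext, refined.chrom, [refined.start], [refined.end]
        )
        # the peak inherits its statistics from its windows: best Poisson p
        # and the strongest window-level NCIS fold (a region-wide average
        # would dilute a narrow summit with its flanks)
        fold = max(c.log2_fold_ncis for c in members)
        # peak-level strand filter on un-extended 5' positions: both
        # flanks of a genuine fragment pileup lie inside the merged peak
        if not strand_filter(
            int(plus[0]), int(minus[0]), params.strand_ratio_max
        ):
            logger.info("peak %s rejected by strand balance", refined)
            continue
        peaks.append(
            Peak(
                interval=refined,
                summit=summit,
                best_p=best.poisson_p,
                q_value=1.0,
                log2_fold_ncis=fold,
                plus_count=int(plus[0]),
                minus_count=int(minus[0]),
                lambda_used=best.lambda_used,
                n_windows=len(members),
            )
        )

    selected = fdr_select(
        peaks, all_pvals, params.fdr_threshold, params.min_log2_fold
    )
    selected.diagnostics = {
        "ncis_r": ncis.r,
        "ncis_background_fraction": ncis.background_fraction,
        "global_lambda": global_lambda,
        "global_threshold": global_thr,
        "background_mu": bg_mu,
        "background_sd": bg_sd,
        "n_windows_tested": int(len(all_pvals)),
        "n_candidate_windows": len(candidates),
        "n_merged_regions": len(merged),
        "n_refined_peaks": len(peaks),
        "n_selected_peaks": len(selected.peaks),
    }
    logger.info(
        "peak calling: r=%.3f lambda=%.3f thr=%d candidates=%d merged=%d "
        "refined=%d selected=%d",
        ncis.r, global_lambda, global_thr, len(candidates), len(merged),
        len(peaks), len(selected.peaks),
    )
    if exclude_in is not None:
        other = exclude_in
        if not other.extended:
            other = extend_reads(deduplicate(other), params.fragment_size)
        selected = exclude_by_other_condition(selected, other, exclude_max)
        logger.info(
            "excluded %d peaks by other-condition signal > %.2f",
            selected.diagnostics.get("excluded_by_other", 0), exclude_max,
        )
    return selected
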