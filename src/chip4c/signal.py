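"""Read-level signal processing for ChIP-seq libraries.

Raw aligned reads become comparable signal in four steps: PCR-duplicate
removal (one read per 5' position and strand), extension of each read to
the library's DNA fragment size (default 300 bp), region quantification in
fragments per million reads per kbp, and quantile normalization across
samples to absorb ChIP-efficiency differences.

The fragment count inside a region is derived from the raw overlap count
by dividing with ``1 + fragment_size / bin_size``: an extended fragment
overlaps that many consecutive bins on average, so the division converts
bin-overlap events back into fragment units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenomicInterval

__all__ = [
    "ReadSet",
    "RegionSignalMatrix",
    "deduplicate",
    "extend_reads",
    "quantify_region",
    "quantify_tss_windows",
    "quantile_normalize",
]


@dataclass
class ReadSet:
    """Stranded read (or extended-fragment) intervals for one library.

    ``library_size`` is the number of retained reads and is used for
    depth normalization; it equals ``len(reads)`` after deduplication.
    """

    reads: pd.DataFrame  # columns: chrom, start, end, strand
    library_size: int
    fragment_size: int = 300
    extended: bool = False

    _index: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_intervals(cls, intervals, fragment_size: int = 300) -> "ReadSet":
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in intervals],
                "start": np.asarray([iv.start for iv in intervals], dtype=np.int64),
                "end": np.asarray([iv.end for iv in intervals], dtype=np.int64),
                "strand": [iv.strand for iv in intervals],
            }
        )
        return cls(reads=df, library_size=len(df), fragment_size=fragment_size)

    def to_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, int(s), int(e), st)
            for c, s, e, st in zip(
                self.reads["chrom"], self.reads["start"],
                self.reads["end"], self.reads["strand"],
            )
        ]

    def chrom_arrays(self, chrom: str, strand: str | None = None):
        """Sorted (starts, ends) arrays for one chromosome.

        The two arrays are sorted independently, which is all interval
        overlap counting needs. Cached per (chrom, strand).
        """
        key = (chrom, strand)
        if key not in self._index:
            df = self.reads
            mask = df["chrom"].values == chrom
            if strand is not None:
                mask &= df["strand"].values == strand
            starts = np.sort(df["start"].values[mask])
            ends = np.sort(df["end"].values[mask])
            self._index[key] = (starts, ends)
        return self._index[key]

    def count_overlaps(self, chrom, win_starts, win_ends, strand=None):
        """Vectorized count of reads overlapping each [start, end) window."""
        starts, ends = self.chrom_arrays(chrom, strand)
        win_starts = np.asarray(win_starts)
        win_ends = np.asarray(win_ends)
        return np.searchsorted(starts, win_ends, side="left") - np.searchsorted(
            ends, win_starts, side="right"
        )


@dataclass
class RegionSignalMatrix:
    """Normalized signal per region per sample (regions x samples)."""

    regions: list[GenomicInterval]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region_id": [f"region_{i + 1}" for i in range(len(self.regions))],
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
            }
        )
        for j, name in enumerate(self.samples):
            df[name] = self.values[:, j]
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def deduplicate(reads: ReadSet | list) -> ReadSet:
    """Keep exactly one read per (chrom, 5' start, strand).

    Multiple reads at the same position and strand almost always come from
    PCR amplification of a single molecule, so only one is retained.
    Output order is deterministic (sorted by chrom, start, strand).
    """
    rs = reads if isinstance(reads, ReadSet) else ReadSet.from_intervals(reads)
    df = rs.reads.drop_duplicates(subset=["chrom", "start", "strand"])
    df = df.sort_values(["chrom", "start", "strand"], kind="mergesort")
    df = df.reset_index(drop=True)
    return ReadSet(reads=df, library_size=len(df), fragment_size=rs.fragment_size)


def extend_reads(readset: ReadSet, fragment_size: int | None = None) -> ReadSet:
    """Extend each read from its 5' end to the DNA fragment size.

    Plus-strand reads become [start, start + L); minus-strand reads become
    [end - L, end), clipped at zero. Unstranded reads are treated as plus.
    """
    L = readset.fragment_size if fragment_size is None else fragment_size
    if L <= 0:
        raise ValueError("fragment_size must be positive")
    df = readset.reads.copy()
    minus = (df["strand"] == "-").values
    starts = df["start"].values.copy()
    ends = df["end"].values.copy()
    new_start = np.where(minus, np.maximum(ends - L, 0), starts)
    new_end = np.where(minus, ends, starts + L)
    df["start"] = new_start
    df["end"] = new_end
    return ReadSet(
        reads=df,
        library_size=readset.library_size,
        fragment_size=L,
        extended=True,
    )


def fragments_from_count(count, fragment_size: int, bin_size: int) -> float:
    """Convert a bin-overlap count into fragment units."""
    return count / (1.0 + fragment_size / bin_size)


def quantify_region(
    readset: ReadSet,
    region: GenomicInterval,
    bin_size: int = 100,
) -> float:
    """Signal in a region, in fragments per million reads per kbp.

    The raw count is the number of extended fragments overlapping the
    region by at least 1 bp; it is converted to fragment units with the
    ``1 + fragment_size/bin_size`` divisor, then normalized by library
    depth (per million reads) and region length (per kbp).
    """
    if readset.library_size == 0:
        raise ValueError("cannot quantify against an empty library (library_size=0)")
    count = float(
        readset.count_overlaps(region.chrom, [region.start], [region.end])[0]
    )
    frags = fragments_from_count(count, readset.fragment_size, bin_size)
    per_million = readset.library_size / 1e6
    per_kbp = len(region) / 1000.0
    return frags / per_million / per_kbp


def quantify_tss_windows(
    readset: ReadSet,
    genes,
    flank_bp: int,
    sample_name: str = "sample",
    bin_size: int = 100,
) -> RegionSignalMatrix:
    """Quantify signal in windows of ±flank_bp around each distinct TSS.

    TSS redundancy key is (chrom, position, strand): transcript isoforms
    sharing a start produce one row. Windows are clipped at zero.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    seen = set()
    regions = []
    for g in genes:
        key = (g.chrom, g.tss, g.strand)
        if key in seen:
            continue
        seen.add(key)
        start = max(g.tss - flank_bp, 0)
        regions.append(GenomicInterval(g.chrom, start, g.tss + flank_bp, g.strand))
    values = np.array(
        [[quantify_region(readset, r, bin_size=bin_size)] for r in regions]
    ).reshape(len(regions), 1)
    return RegionSignalMatrix(regions=regions, samples=[sample_name], values=values)


def quantile_normalize(matrix):
    """Quantile-normalize sample columns to a common distribution.

    Each column's order statistics are replaced by the across-column mean
    of order statistics, preserving within-column ranking. Ties receive the
    mean of the order-statistic means they span (mid-rank convention), so
    the result is deterministic and symmetric in the tied entries.

    Accepts and returns either a 2-D array or a :class:`RegionSignalMatrix`.
    """
    if isinstance(matrix, RegionSignalMatrix):
        out = quantile_normalize(matrix.values)
        return replace(matrix, values=out)
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 sample columns")
    sorted_cols = np.sort(values, axis=0)
    ref = sorted_cols.mean(axis=1)  # mean of order statistics
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # mid-rank tie handling: tied values share the mean of their refs
        ser = pd.Series(assigned)
        out[:, j] = ser.groupby(col).transform("mean").values
    return out
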