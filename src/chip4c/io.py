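"""Readers and writers for the genomic text formats the pipeline touches.

All coordinates are 0-based half-open internally (BED-native). refFlat
txStart is already 0-based, so no conversion is needed on read; conversion
for 1-based formats, if ever added, happens only at the format boundary.
Chromosome names are taken verbatim — no "chr" normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ExpressionRecord",
    "FormatError",
    "read_bed",
    "write_bed",
    "read_refflat",
    "write_refflat",
    "write_bedgraph",
    "read_bedgraph",
]

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded.

    ``start`` is inclusive, ``end`` exclusive; ``strand`` is one of
    ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A transcript model in refFlat terms: span plus sorted exon blocks."""

    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/-: {self.strand!r}")
        prev_end = None
        for ex in self.exons:
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(
                    f"exon {ex} outside transcript span "
                    f"[{self.tx_start}, {self.tx_end})"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start on '+', tx_end on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        """Transcript end (the non-TSS extremity)."""
        return self.tx_end if self.strand == "+" else self.tx_start


@dataclass
class ExpressionRecord:
    """Normalized expression (NE) of one transcript anchored at its TSS.

    NE = c * reads_bp / (total_mapped_bp * length_bp) with c = 1e7 by
    convention; NE is zero exactly when the raw read count is zero.
    """

    transcript_id: str
    chrom: str
    tss: int
    raw_read_bp_count: float
    ne: float

    def __post_init__(self) -> None:
        if self.ne < 0:
            raise ValueError("NE must be non-negative")
        if (self.ne == 0) != (self.raw_read_bp_count == 0):
            raise ValueError("NE is zero iff the raw count is zero")


def read_bed(path) -> list[GenomicInterval]:
    """Parse a BED3/BED6 file into intervals (0-based half-open).

    Column 6, when present, is taken as the strand. Malformed lines raise
    :class:`FormatError` naming the line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals, path, names=None, scores=None) -> None:
    """Write intervals as BED6 (BED3 if all strands are '.' and no names)."""
    bed6 = names is not None or scores is not None or any(
        iv.strand != "." for iv in intervals
    )
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if bed6:
                name = names[i] if names is not None else f"region_{i + 1}"
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_refflat(path) -> list[GeneModel]:
    """Parse a refFlat annotation file into :class:`GeneModel` objects.

    Layout: geneName, name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds (starts/ends comma-separated,
    trailing comma tolerated). Coordinates are 0-based half-open already.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise FormatError(f"{path}:{lineno}: expected 11 columns, got {len(f)}")
            strand = f[3]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            n_exons = int(f[8])
            starts = [int(x) for x in f[9].rstrip(",").split(",") if x]
            ends = [int(x) for x in f[10].rstrip(",").split(",") if x]
            if len(starts) != n_exons or len(ends) != n_exons:
                raise FormatError(
                    f"{path}:{lineno}: exonCount={n_exons} but "
                    f"{len(starts)} starts / {len(ends)} ends listed"
                )
            try:
                exons = [
                    GenomicInterval(f[2], s, e, strand)
                    for s, e in zip(starts, ends)
                ]
                genes.append(
                    GeneModel(
                        gene_name=f[0],
                        transcript_id=f[1],
                        chrom=f[2],
                        strand=strand,
                        tx_start=int(f[4]),
                        tx_end=int(f[5]),
                        cds_start=int(f[6]),
                        cds_end=int(f[7]),
                        exons=exons,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_refflat(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons) + ","
            ends = ",".join(str(e.end) for e in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.gene_name,
                        g.transcript_id,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        str(g.cds_start),
                        str(g.cds_end),
                        str(len(g.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


def write_bedgraph(bins, path, header=None) -> None:
    """Write per-bin values as bedGraph, merging runs of equal value.

    ``bins`` is an iterable of ``(chrom, start, end, value)`` sorted by
    (chrom, start) and non-overlapping. Runs of adjacent bins with equal
    value collapse to one line; zero-valued runs are omitted.
    """
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        run = None  # (chrom, start, end, value)
        prev = None
        for chrom, start, end, value in bins:
            if prev is not None and prev[0] == chrom and start < prev[2]:
                raise ValueError(
                    f"overlapping bins: {chrom}:{start} < previous end {prev[2]}"
                )
            prev = (chrom, start, end)
            if run is not None and (
                chrom != run[0] or start != run[2] or value != run[3]
            ):
                if run[3] != 0:
                    fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]:g}\n")
                run = None
            if run is None:
                run = (chrom, start, end, value)
            else:
                run = (run[0], run[1], end, run[3])
        if run is not None and run[3] != 0:
            fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]:g}\n")


def read_bedgraph(path) -> list[tuple]:
    """Read a bedGraph file back as (chrom, start, end, value) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            out.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return out
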