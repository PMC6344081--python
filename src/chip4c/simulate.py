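"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the structure of the real inputs without any
download: ChIP read sets (Poisson background on both strands plus planted
peaks whose plus/minus 5' reads are offset by half a strand shift — the
bimodal pattern a real protein-DNA crosslink produces — and an IgG-like
control at its own depth), 4C fragment-end profiles (negative-binomial
counts around a monotone distance-decay curve with planted differential
contact blocks), and refFlat gene annotations with log-normal expression
tables carrying planted fold changes.

Every generator is a pure function of its spec plus seed: the same seed
reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fourc import FourCProfile
from .io import GeneModel, GenomicInterval, ExpressionRecord
from .signal import ReadSet

__all__ = [
    "PlantedPeak",
    "ChipSimSpec",
    "PlantedContact",
    "FourCSimSpec",
    "simulate_chip",
    "simulate_fourc",
    "simulate_annotation_and_expression",
]


@dataclass
class PlantedPeak:
    chrom: str
    position: int  # center
    width: int = 400
    fold: float = 10.0
    strand_shift: int | None = None  # None -> fragment_size
    single_strand: bool = False  # artifact mode: all extra reads on '+'

    def truth_interval(self) -> GenomicInterval:
        half = self.width // 2
        return GenomicInterval(
            self.chrom, max(self.position - half, 0), self.position + half
        )


@dataclass
class ChipSimSpec:
    """Conditions for one simulated ChIP experiment.

    ``library_size`` is the expected number of background sample reads;
    ``background_rate`` (reads per bp, both strands combined) is derived
    from it unless given explicitly. The control is background-only at
    ``control_depth_ratio`` times the sample depth.
    """

    genome: list = field(default_factory=lambda: [("chr1", 10_000_000)])
    library_size: int = 1_000_000
    background_rate: float | None = None
    planted_peaks: list = field(default_factory=list)
    fragment_size: int = 300
    read_length: int = 36
    control_depth_ratio: float = 0.7
    seed: int = 0

    def rate(self) -> float:
        if self.background_rate is not None:
            return self.background_rate
        total_bp = sum(length for _, length in self.genome)
        return self.library_size / total_bp

    def validate(self) -> None:
        if self.rate() <= 0:
            raise ValueError("background rate must be positive")
        lengths = dict(self.genome)
        truth = sorted(
            (p.truth_interval() for p in self.planted_peaks),
            key=lambda iv: (iv.chrom, iv.start),
        )
        for a, b in zip(truth, truth[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping planted peaks: {a} / {b}")
        for p in self.planted_peaks:
            if p.chrom not in lengths:
                raise ValueError(f"planted peak on unknown chrom {p.chrom}")
            if not 0 <= p.position < lengths[p.chrom]:
                raise ValueError(f"planted peak outside genome: {p}")


def _reads_frame(chroms, fives, strands, read_length, chrom_len):
    """Build a read interval table from 5' positions and strands."""
    fives = np.asarray(fives, dtype=np.int64)
    strands = np.asarray(strands)
    starts = np.where(strands == "+", fives, fives - read_length + 1)
    starts = np.clip(starts, 0, None)
    ends = np.where(strands == "+", fives + read_length, fives + 1)
    ends = np.minimum(ends, chrom_len)
    ends = np.maximum(ends, starts + 1)
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "strand": strands}
    )


def simulate_chip(spec: ChipSimSpec):
    """Simulate sample and control ChIP libraries with planted peaks.

    Returns ``(sample ReadSet, control ReadSet, truth intervals)``.
    Background read 5' positions follow a Poisson process at the spec's
    rate, split evenly between strands; inside each planted peak, extra
    reads at (fold - 1) x background density are added with plus-strand
    5' ends shifted -shift/2 and minus-strand +shift/2 from the peak
    positions (shift defaults to the fragment size). ``single_strand``
    peaks put all extra reads on the plus strand, mimicking an
    amplification artifact rather than a crosslinked fragment pileup.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate()
    frames_s, frames_c = [], []
    peaks_by_chrom: dict[str, list] = {}
    for p in spec.planted_peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, length in spec.genome:
        for rs_rate, frames, with_peaks in (
            (rate, frames_s, True),
            (rate * spec.control_depth_ratio, frames_c, False),
        ):
            fives, strands = [], []
            for strand in ("+", "-"):
                n = rng.poisson(rs_rate / 2.0 * length)
                pos = rng.integers(0, length, size=n)
                fives.append(pos)
                strands.append(np.full(n, strand))
            if with_peaks:
                for peak in peaks_by_chrom.get(chrom, []):
                    shift = (
                        spec.fragment_size
                        if peak.strand_shift is None
                        else peak.strand_shift
                    )
                    per_strand = (peak.fold - 1.0) * rate / 2.0 * peak.width
                    half = peak.width // 2
                    lo, hi = peak.position - half, peak.position + half
                    if peak.single_strand:
                        n_plus = rng.poisson(2 * per_strand)
                        n_minus = 0
                    else:
                        n_plus = rng.poisson(per_strand)
                        n_minus = rng.poisson(per_strand)
                    plus = rng.integers(lo, hi, size=n_plus) - shift // 2
                    minus = rng.integers(lo, hi, size=n_minus) + shift // 2
                    fives.append(np.clip(plus, 0, length - 1))
                    strands.append(np.full(n_plus, "+"))
                    fives.append(np.clip(minus, 0, length - 1))
                    strands.append(np.full(n_minus, "-"))
            fives = np.concatenate(fives) if fives else np.array([], dtype=np.int64)
            strands = (
                np.concatenate(strands) if strands else np.array([], dtype="<U1")
            )
            frames.append(
                _reads_frame(chrom, fives, strands, spec.read_length, length)
            )
    sample_df = pd.concat(frames_s, ignore_index=True)
    control_df = pd.concat(frames_c, ignore_index=True)
    sample = ReadSet(
        reads=sample_df, library_size=len(sample_df),
        fragment_size=spec.fragment_size,
    )
    control = ReadSet(
        reads=control_df, library_size=len(control_df),
        fragment_size=spec.fragment_size,
    )
    truth = [p.truth_interval() for p in spec.planted_peaks]
    return sample, control, truth


@dataclass
class PlantedContact:
    start_index: int
    n_ends: int
    fold: float = 10.0
    winner: str = "B"  # condition with the higher contact frequency


@dataclass
class FourCSimSpec:
    """Conditions for a simulated two-condition 4C viewpoint profile."""

    n_fragment_ends: int = 5000
    chrom: str = "chr11"
    spacing_low: int = 300
    spacing_high: int = 1500
    blind_fraction: float = 0.3
    viewpoint_index: int | None = None  # None -> middle
    decay_amplitude: float = 500.0
    decay_d0: float = 100_000.0
    decay_alpha: float = 1.0
    nb_size: float = 5.0  # negative-binomial overdispersion (smaller = noisier)
    planted_contacts: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_fragment_ends < 3:
            raise ValueError("need at least three fragment ends")
        for c in self.planted_contacts:
            if c.start_index < 0 or c.start_index + c.n_ends > self.n_fragment_ends:
                raise ValueError(f"planted contact outside profile: {c}")
            if c.winner not in ("A", "B"):
                raise ValueError("contact winner must be 'A' or 'B'")


def simulate_fourc(spec: FourCSimSpec):
    """Simulate paired 4C profiles with planted differential contacts.

    Returns ``(profile_a, profile_b, truth)``. Counts are negative-
    binomial around a monotone distance-decay mean
    ``A / (1 + d/d0)^alpha`` from the viewpoint; planted contact blocks
    multiply the winning condition's mean by their fold. Blind flags are
    assigned independently of signal at the stated fraction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_fragment_ends
    gaps = rng.integers(spec.spacing_low, spec.spacing_high, size=n)
    positions = 10_000 + np.cumsum(gaps)
    vp = spec.viewpoint_index if spec.viewpoint_index is not None else n // 2
    dist = np.abs(positions - positions[vp])
    mean = spec.decay_amplitude / (1.0 + dist / spec.decay_d0) ** spec.decay_alpha
    mean = np.maximum(mean, 0.5)
    blind = rng.random(n) < spec.blind_fraction
    mean_a = mean.copy()
    mean_b = mean.copy()
    for c in spec.planted_contacts:
        sl = slice(c.start_index, c.start_index + c.n_ends)
        if c.winner == "A":
            mean_a[sl] *= c.fold
        else:
            mean_b[sl] *= c.fold
    size = spec.nb_size
    counts = []
    for m in (mean_a, mean_b):
        p = size / (size + m)
        counts.append(rng.negative_binomial(size, p).astype(float))
    prof_a = FourCProfile(
        chrom=spec.chrom, positions=positions, blind=blind, counts=counts[0]
    )
    prof_b = FourCProfile(
        chrom=spec.chrom, positions=positions, blind=blind, counts=counts[1]
    )
    truth = pd.DataFrame(
        [
            {
                "start_index": c.start_index,
                "end_index": c.start_index + c.n_ends,
                "start": int(positions[c.start_index]),
                "end": int(positions[c.start_index + c.n_ends - 1]) + 1,
                "fold": c.fold,
                "winner": c.winner,
            }
            for c in spec.planted_contacts
        ],
        columns=["start_index", "end_index", "start", "end", "fold", "winner"],
    )
    return prof_a, prof_b, truth


def simulate_annotation_and_expression(
    n_genes: int,
    genome,
    fc_spec=((0.8, 0.0), (0.1, 2.0), (0.1, -2.0)),
    seed: int = 0,
    expression_noise_sd: float = 0.1,
):
    """Simulate a refFlat-style annotation and paired expression tables.

    Genes are multi-exon, on both strands, placed without overlap by
    slotting them along each chromosome. Condition-A expression (NE) is
    log-normal; condition B multiplies it by 2**lfc with the planted lfc
    drawn from ``fc_spec`` (fractions and log2 fold values) plus
    log-normal measurement noise. Returns
    ``(genes, expression_a, expression_b, truth)``.
    """
    rng = np.random.default_rng(seed)
    total_bp = sum(length for _, length in genome)
    slot = total_bp // n_genes
    if slot < 3000:
        raise ValueError("genome too small for the requested gene count")
    genes: list[GeneModel] = []
    offsets = []
    acc = 0
    for chrom, length in genome:
        offsets.append((chrom, acc, length))
        acc += length
    fracs = np.array([f for f, _ in fc_spec], dtype=float)
    lfcs = np.array([v for _, v in fc_spec], dtype=float)
    fracs = fracs / fracs.sum()
    planted = rng.choice(lfcs, size=n_genes, p=fracs)
    expr_a, expr_b = [], []
    truth_rows = []
    total_mapped_bp = 1e9
    for i in range(n_genes):
        slot_start = i * slot
        chrom = None
        for c, off, length in offsets:
            if off <= slot_start < off + length:
                chrom, chrom_off, chrom_len = c, off, length
                break
        local = slot_start - chrom_off
        gene_len = int(rng.integers(2000, min(slot - 500, 20000)))
        tx_start = local + int(rng.integers(0, max(slot - gene_len - 100, 1)))
        tx_start = min(tx_start, chrom_len - gene_len - 1)
        tx_end = tx_start + gene_len
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 9))
        cuts = np.sort(rng.choice(np.arange(1, gene_len), 2 * n_exons - 2,
                                  replace=False)) if n_exons > 1 else np.array([], int)
        bounds = np.r_[0, cuts, gene_len]
        exons = [
            GenomicInterval(chrom, tx_start + int(bounds[2 * k]),
                            tx_start + int(bounds[2 * k + 1]), strand)
            for k in range(n_exons)
        ]
        name = f"GENE{i + 1}"
        tid = f"TX{i + 1}"
        gene = GeneModel(
            gene_name=name, transcript_id=tid, chrom=chrom, strand=strand,
            tx_start=tx_start, tx_end=tx_end,
            cds_start=tx_start, cds_end=tx_end, exons=exons,
        )
        genes.append(gene)
        ne_a = float(rng.lognormal(mean=np.log(0.5), sigma=1.0))
        noise = float(rng.lognormal(mean=0.0, sigma=expression_noise_sd))
        ne_b = ne_a * 2.0 ** planted[i] * noise
        for ne, acc_list in ((ne_a, expr_a), (ne_b, expr_b)):
            raw = ne * total_mapped_bp * gene_len / 1e7
            acc_list.append(
                ExpressionRecord(
                    transcript_id=tid, chrom=chrom, tss=gene.tss,
                    raw_read_bp_count=raw, ne=ne,
                )
            )
        truth_rows.append(
            {"transcript_id": tid, "gene": name, "planted_log2_fc": planted[i]}
        )
    return genes, expr_a, expr_b, pd.DataFrame(truth_rows)


def write_expression_tsv(records, path) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "chrom": r.chrom,
                "tss": r.tss,
                "raw_read_bp_count": r.raw_read_bp_count,
                "ne": r.ne,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return [
        ExpressionRecord(
            transcript_id=str(r.transcript_id), chrom=str(r.chrom),
            tss=int(r.tss), raw_read_bp_count=float(r.raw_read_bp_count),
            ne=float(r.ne),
        )
        for r in df.itertuples()
    ]
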