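"""Pipeline orchestration: run the analysis stages from one config.

Stages run in dependency order — signal/peaks → other-condition
exclusion → mark classification → annotation — with the 4C branch
independent. Every output file starts with a provenance line (package
version, config hash, seed) and reruns with the same config reproduce
identical outputs for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotate import annotate_peaks_frame, enhancer_overlap, fisher_enrichment
from .diffmarks import classify_peak_h3k27ac
from .fourc import (
    call_contacts,
    contact_regions_frame,
    normalize_profiles,
    rank_window_test,
    read_fourc_table,
    remove_excluded_ends,
)
from .io import GenomicInterval, read_bed, read_refflat
from .peaks import PeakCallingParams, call_peaks
from .signal import ReadSet, deduplicate, extend_reads, quantify_region
from .simulate import (
    ChipSimSpec,
    FourCSimSpec,
    PlantedContact,
    PlantedPeak,
    read_expression_tsv,
    simulate_chip,
    simulate_fourc,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "genome": [["chr1", 10_000_000]],
    "peaks": {},  # PeakCallingParams overrides
    "fourc": {"window": 21, "trim": 0.10, "fdr": 0.01},
    "classify": {"fc_cutoff": 1.0, "floor_h3k27me3": 0.5, "floor_h3k4me3": 5.0,
                 "exclude_max": 0.76, "flank": 5000},
    "inputs": {},
    "out_dir": "results",
}


def load_config(path=None, overrides=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                for k2, v2 in val.items():
                    if cfg[key].get(k2) != v2:
                        logger.info("config override: %s.%s = %r", key, k2, v2)
                    cfg[key][k2] = v2
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    """Hash of the analysis-relevant config (output location excluded)."""
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def provenance(cfg: dict) -> str:
    return (
        f"# chip4c {__version__} config={config_hash(cfg)} seed={cfg['seed']}"
    )


def _read_readset(path, fragment_size) -> ReadSet:
    return ReadSet.from_intervals(read_bed(path), fragment_size=fragment_size)


def run_pipeline(cfg: dict) -> Path:
    """Run all stages whose inputs are configured; returns the out dir."""
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    header = provenance(cfg)
    genome = [(c, int(n)) for c, n in cfg["genome"]]
    inputs = cfg["inputs"]
    params = PeakCallingParams(**cfg.get("peaks", {}))

    def need(name):
        path = inputs.get(name)
        if path is None:
            return None
        if not Path(path).exists():
            raise FileNotFoundError(f"stage input {name!r} missing: {path}")
        return path

    peaks = None
    if need("sample_bed") and need("control_bed"):
        sample = _read_readset(inputs["sample_bed"], params.fragment_size)
        control = _read_readset(inputs["control_bed"], params.fragment_size)
        exclude = None
        if need("exclude_bed"):
            exclude = _read_readset(inputs["exclude_bed"], params.fragment_size)
        peaks = call_peaks(
            sample, control, genome, params,
            exclude_in=exclude,
            exclude_max=cfg["classify"]["exclude_max"],
        )
        peaks.write_bed(out / "peaks.bed", header=header)
        with open(out / "peaks.log", "w") as fh:
            fh.write(header + "\n")
            for k, v in peaks.diagnostics.items():
                fh.write(f"{k}\t{v}\n")
        logger.info("callpeaks: %d peaks -> %s", len(peaks), out / "peaks.bed")

        if need("signal_day0_bed") and need("signal_day10_bed"):
            flank = int(cfg["classify"]["flank"])
            s0 = extend_reads(deduplicate(
                _read_readset(inputs["signal_day0_bed"], params.fragment_size)))
            s10 = extend_reads(deduplicate(
                _read_readset(inputs["signal_day10_bed"], params.fragment_size)))
            ids, v0, v10 = [], [], []
            for i, p in enumerate(peaks):
                center = p.interval.midpoint
                region = GenomicInterval(
                    p.interval.chrom, max(center - flank, 0), center + flank
                )
                ids.append(f"peak_{i + 1}")
                v0.append(quantify_region(s0, region))
                v10.append(quantify_region(s10, region))
            calls = classify_peak_h3k27ac(
                ids, v0, v10, fc_cutoff=cfg["classify"]["fc_cutoff"]
            )
            with open(out / "peak_mark_changes.tsv", "w") as fh:
                fh.write(header + "\n")
                fh.write("peak_id\tlog2_fc\tlabel\n")
                for c in calls:
                    fh.write(f"{c.region_id}\t{c.log2_fc:.4f}\t{c.label}\n")
            logger.info("classify: %d peaks labelled", len(calls))

        if need("refflat"):
            genes = read_refflat(inputs["refflat"])
            expr_a = expr_b = None
            if need("expression_a") and need("expression_b"):
                expr_a = read_expression_tsv(inputs["expression_a"])
                expr_b = read_expression_tsv(inputs["expression_b"])
            frame = annotate_peaks_frame(
                [p.interval for p in peaks], genes, expr_a, expr_b
            )
            with open(out / "annotated_peaks.tsv", "w") as fh:
                fh.write(header + "\n")
                frame.to_csv(fh, sep="\t", index=False)
            logger.info("annotate: %d peaks annotated", len(frame))

        if need("enhancers_bed"):
            enhancers = read_bed(inputs["enhancers_bed"])
            hit_peaks, hit_enh = enhancer_overlap(
                [p.interval for p in peaks], enhancers
            )
            bound = np.zeros(len(enhancers), dtype=bool)
            hit_keys = {(e.chrom, e.start, e.end) for e in hit_enh}
            for i, e in enumerate(enhancers):
                bound[i] = (e.chrom, e.start, e.end) in hit_keys
            with open(out / "enhancer_overlap.tsv", "w") as fh:
                fh.write(header + "\n")
                fh.write("n_peaks\tn_overlapping_peaks\tn_enhancers\tn_hit\n")
                fh.write(
                    f"{len(peaks)}\t{len(hit_peaks)}\t{len(enhancers)}"
                    f"\t{len(hit_enh)}\n"
                )
            logger.info(
                "enhancers: %d/%d peaks overlap", len(hit_peaks), len(peaks)
            )

    if need("fourc_table"):
        prof_a, prof_b = read_fourc_table(inputs["fourc_table"])
        vp = inputs.get("fourc_viewpoint")
        if vp is not None:
            prof_a = remove_excluded_ends(prof_a, int(vp))
            prof_b = remove_excluded_ends(prof_b, int(vp))
        prof_a, prof_b = normalize_profiles(prof_a, prof_b)
        fc_cfg = cfg["fourc"]
        windows = rank_window_test(
            prof_a, prof_b, window=int(fc_cfg["window"]), trim=float(fc_cfg["trim"])
        )
        regions = call_contacts(windows, fdr=float(fc_cfg["fdr"]))
        with open(out / "fourc_contacts.tsv", "w") as fh:
            fh.write(header + "\n")
            contact_regions_frame(regions).to_csv(fh, sep="\t", index=False)
        logger.info(
            "fourc: %d windows tested, %d contact regions",
            len(windows), len(regions),
        )
    return out


def make_demo_inputs(out_dir, seed: int = 0) -> dict:
    """Generate a self-contained synthetic demo dataset; returns a config."""
    from .io import write_bed, write_refflat
    from .simulate import (
        simulate_annotation_and_expression,
        write_expression_tsv,
    )
    from .fourc import write_fourc_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genome = [("chr1", 2_000_000)]
    centers = np.arange(100_000, 1_950_000, 90_000) + rng.integers(-20_000, 20_000, 21)
    peaks = [PlantedPeak("chr1", int(c), width=400, fold=10.0) for c in centers]
    spec = ChipSimSpec(genome=genome, library_size=200_000,
                       planted_peaks=peaks, seed=seed)
    sample, control, truth = simulate_chip(spec)
    write_bed(sample.to_intervals(), out / "sample.bed")
    write_bed(control.to_intervals(), out / "control.bed")
    write_bed(truth, out / "truth_peaks.bed")
    # day-0 / day-10 signal libraries: day-10 enriched at half the peaks
    gained = peaks[::2]
    spec0 = ChipSimSpec(genome=genome, library_size=150_000, seed=seed + 1)
    day0, _, _ = simulate_chip(spec0)
    spec10 = ChipSimSpec(genome=genome, library_size=150_000,
                         planted_peaks=[PlantedPeak(p.chrom, p.position,
                                                    width=1000, fold=8.0)
                                        for p in gained],
                         seed=seed + 2)
    day10, _, _ = simulate_chip(spec10)
    write_bed(day0.to_intervals(), out / "h3k27ac_day0.bed")
    write_bed(day10.to_intervals(), out / "h3k27ac_day10.bed")
    genes, expr_a, expr_b, truth_expr = simulate_annotation_and_expression(
        40, genome, seed=seed + 3
    )
    write_refflat(genes, out / "genes.refflat")
    write_expression_tsv(expr_a, out / "expression_day0.tsv")
    write_expression_tsv(expr_b, out / "expression_day10.tsv")
    truth_expr.to_csv(out / "truth_expression.tsv", sep="\t", index=False)
    # enhancers near one third of the planted peaks
    enh = [
        GenomicInterval("chr1", int(c) - 200, int(c) + 200)
        for c in centers[::3]
    ]
    write_bed(enh, out / "enhancers.bed")
    fspec = FourCSimSpec(
        n_fragment_ends=2000, seed=seed + 4,
        planted_contacts=[PlantedContact(start_index=1500, n_ends=30,
                                         fold=10.0, winner="B")],
    )
    pa, pb, truth_4c = simulate_fourc(fspec)
    write_fourc_table(pa, pb, out / "fourc.tsv")
    truth_4c.to_csv(out / "truth_fourc.tsv", sep="\t", index=False)
    cfg = load_config(overrides={
        "seed": seed,
        "genome": [list(g) for g in genome],
        "out_dir": str(out / "results"),
    })
    cfg["inputs"] = {
        "sample_bed": str(out / "sample.bed"),
        "control_bed": str(out / "control.bed"),
        "signal_day0_bed": str(out / "h3k27ac_day0.bed"),
        "signal_day10_bed": str(out / "h3k27ac_day10.bed"),
        "refflat": str(out / "genes.refflat"),
        "expression_a": str(out / "expression_day0.tsv"),
        "expression_b": str(out / "expression_day10.tsv"),
        "enhancers_bed": str(out / "enhancers.bed"),
        "fourc_table": str(out / "fourc.tsv"),
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return cfg
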