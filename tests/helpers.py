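from chip4c.io import GeneModel, GenomicInterval


def make_gene(chrom="chr1", strand="+", tx_start=1000, tx_end=5000,
              exons=None, name="G", tid=None):
    exons = exons or [(tx_start, tx_end)]
    return GeneModel(
        gene_name=name,
        transcript_id=tid or name + "_t1",
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=tx_start,
        cds_end=tx_end,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )
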