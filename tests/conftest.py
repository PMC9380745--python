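import numpy as np
import pytest

from clipsplice.genome_model import Annotation, Gene, GenomicInterval, Transcript


def make_tx(tid, exons, strand="+", chrom="chr1", gene_id=None, cds=None,
            biotype="protein_coding"):
    """Build a Transcript from (start, end) exon tuples."""
    gene_id = gene_id or f"gene_{tid}"
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    return Transcript(
        tid, gene_id, ivs,
        cds_start=cds[0] if cds else None,
        cds_end=cds[1] if cds else None,
        biotype=biotype,
    )


def make_gene(gid, tx_exon_lists, strand="+", chrom="chr1", cds=None,
              biotype="protein_coding"):
    txs = [
        make_tx(f"{gid}.t{i + 1}", exons, strand, chrom, gid, cds, biotype)
        for i, exons in enumerate(tx_exon_lists)
    ]
    return Gene(gid, txs, biotype)


def random_transcript(rng, tid="tx", chrom="chr1", strand=None, coding=True,
                      max_exons=6):
    """Random valid transcript; coding ones get a CDS inside the exon union."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(0, 500))
    exons = []
    for _ in range(n):
        length = int(rng.integers(20, 200))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(30, 300))
    cds = None
    if coding and n >= 1:
        first, last = exons[0], exons[-1]
        cs = first[0] + int(rng.integers(0, first[1] - first[0]))
        ce = last[1] - int(rng.integers(0, last[1] - last[0]))
        if cs < ce:
            cds = (cs, ce)
    return make_tx(tid, exons, strand, chrom, cds=cds)


@pytest.fixture
def rng():
    return np.random.default_rng(20220909)


def brute_force_feature_label(t, pos):
    """Per-base oracle: feature label of genomic position pos in transcript t,
    or None outside the transcript span."""
    if not (t.start <= pos < t.end):
        return None
    in_exon = any(e.start <= pos < e.end for e in t.exons)
    if not in_exon:
        return "intron"
    if not t.is_coding:
        return "exon"
    if t.cds_start <= pos < t.cds_end:
        return "cds"
    before_cds = pos < t.cds_start
    if t.strand == "+":
        return "five_prime_utr" if before_cds else "three_prime_utr"
    return "three_prime_utr" if before_cds else "five_prime_utr"
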