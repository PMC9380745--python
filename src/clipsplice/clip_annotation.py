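"""Annotation of filtered peaks against transcript models.

Assigns each peak a feature category (5'UTR / exon / intron / 3'UTR /
intergenic), an exon-ordinal class (first/mid/last exon or intron) relative
to a representative transcript, and a junction-spanning flag; builds metagene
profiles around exon-intron boundaries and enrichment-gated biotype read
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clip_peaks import ReadSet
from .genome_model import (
    Annotation,
    BIOTYPE_BUCKETS,
    Gene,
    GenomicInterval,
    Transcript,
    aggregate_biotype,
    derive_features,
)

#: Feature-label precedence used to break ties between transcripts whose
#: dominant features overlap the peak by the same number of bases. Coding
#: exon overlap dominates; a non-coding exon ranks with the coding exon.
DEFAULT_PRECEDENCE = ("cds", "exon", "five_prime_utr", "three_prime_utr", "intron")

_CATEGORY_OF_LABEL = {
    "cds": "exon",
    "exon": "exon",
    "five_prime_utr": "5utr",
    "three_prime_utr": "3utr",
    "intron": "intron",
}

EXON_POSITION_CLASSES = (
    "first_exon", "mid_exon", "last_exon",
    "first_intron", "mid_intron", "last_intron",
)


@dataclass
class PeakAnnotation:
    peak: GenomicInterval
    gene_id: str | None
    category: str  # one of {"5utr", "exon", "intron", "3utr", "intergenic"}
    exon_position: str | None = None  # EXON_POSITION_CLASSES or None
    junction_spanning: bool = False
    biotype: str | None = None


@dataclass
class MetageneProfile:
    """Mean coverage per boundary at relative positions -W..+W.

    Position 0 is the first intronic base in transcript orientation for a
    5' splice site profile (exon end | intron start); for a 3' splice site
    profile position 0 is the last intronic base, so negative positions are
    always on the exon-proximal 5' side of the axis.
    """

    positions: np.ndarray
    mean_coverage: np.ndarray
    n_boundaries: int


def representative_transcript(gene: Gene) -> Transcript:
    """Transcript with the most exons; ties broken by longest span, then id."""
    return max(gene.transcripts, key=lambda t: (t.n_exons, t.span.width, t.id))


def _feature_overlaps(peak: GenomicInterval, t: Transcript) -> dict[str, int]:
    """Total base overlap of the peak with each feature label of t."""
    out: dict[str, int] = {}
    for iv, label in derive_features(t):
        ov = iv.overlap_len(peak.start, peak.end)
        if ov > 0:
            out[label] = out.get(label, 0) + ov
    return out


def assign_category(
    peak: GenomicInterval,
    annotation: Annotation,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> PeakAnnotation:
    """Assign a peak its dominant feature category and owning gene.

    Candidate transcripts are same-strand transcripts overlapping the peak.
    Per transcript the dominant feature is the label with the largest base
    overlap (ties within a transcript broken by ``precedence``); across
    transcripts the winner is the largest dominant overlap, ties again broken
    by ``precedence``. No overlapping transcript yields "intergenic".
    """
    rank = {lab: i for i, lab in enumerate(precedence)}
    best = None  # (overlap, -rank, label, transcript)
    candidates = sorted(
        annotation.overlapping_transcripts(peak.chrom, peak.start, peak.end, peak.strand),
        key=lambda t: t.id,  # orientation-independent tie-break
    )
    for t in candidates:
        ovs = _feature_overlaps(peak, t)
        if not ovs:
            continue
        label, ov = max(ovs.items(), key=lambda kv: (kv[1], -rank.get(kv[0], len(rank))))
        key = (ov, -rank.get(label, len(rank)))
        if best is None or key > best[0]:
            best = (key, label, t)
    if best is None:
        return PeakAnnotation(peak, None, "intergenic")
    _, label, t = best
    gene = annotation.genes[t.gene_id]
    return PeakAnnotation(
        peak, gene.id, _CATEGORY_OF_LABEL[label],
        biotype=aggregate_biotype(gene.biotype),
    )


def classify_exon_position(peak: GenomicInterval, gene: Gene) -> str | None:
    """First/mid/last exon-or-intron class of the peak within a gene.

    Uses the gene's representative transcript; genes whose representative
    transcript has fewer than three exons yield ``None``, as do peaks not
    overlapping the representative transcript. "first" is the 5'-most element
    in transcript orientation (strand-aware).
    """
    t = representative_transcript(gene)
    if t.n_exons < 3:
        return None
    best = None  # (overlap, kind, ordinal, n)
    exons = t.exons_5to3()
    introns = t.introns_5to3()
    for i, e in enumerate(exons):
        ov = e.overlap_len(peak.start, peak.end)
        if ov > 0 and (best is None or ov > best[0]):
            best = (ov, "exon", i, len(exons))
    for i, iv in enumerate(introns):
        ov = iv.overlap_len(peak.start, peak.end)
        if ov > 0 and (best is None or ov > best[0]):
            best = (ov, "intron", i, len(introns))
    if best is None:
        return None
    _, kind, i, n = best
    pos = "first" if i == 0 else ("last" if i == n - 1 else "mid")
    return f"{pos}_{kind}"


def _boundaries_of(t: Transcript, min_span: int = 0):
    """Exon-intron boundary coordinates B (first intronic base) per intron.

    Yields (exonic_end, intronic_start) genomic pairs for both the donor and
    acceptor side of every intron of the transcript.
    """
    for intron in t.introns:
        # left edge: exon | intron at intron.start; right edge at intron.end
        yield intron.start
        yield intron.end  # NB: at intron.end the intron is to the LEFT


def flag_junction_spanning(
    peaks: Sequence[GenomicInterval],
    annotation: Annotation,
    min_span: int = 1,
) -> tuple[list[bool], float]:
    """Flag peaks that straddle an annotated exon-intron boundary.

    A peak is flagged when it covers at least ``min_span`` nt on each side of
    some boundary of an overlapping same-strand transcript. Returns the
    per-peak flags and the flagged fraction (0.0 for an empty input).
    """
    flags = []
    for p in peaks:
        hit = False
        for t in annotation.overlapping_transcripts(p.chrom, p.start, p.end, p.strand):
            for b in _boundaries_of(t):
                if p.start <= b - min_span and p.end >= b + min_span:
                    hit = True
                    break
            if hit:
                break
        flags.append(hit)
    frac = sum(flags) / len(flags) if flags else 0.0
    return flags, frac


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    annotation: Annotation,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    min_span: int = 1,
) -> list[PeakAnnotation]:
    """Full per-peak annotation: category, exon ordinal class, junction flag."""
    out = []
    flags, _ = flag_junction_spanning(peaks, annotation, min_span)
    for p, flag in zip(peaks, flags):
        pa = assign_category(p, annotation, precedence)
        if pa.gene_id is not None:
            pa.exon_position = classify_exon_position(p, annotation.genes[pa.gene_id])
        pa.junction_spanning = flag and pa.category in ("exon", "intron")
        out.append(pa)
    return out


def metagene_profile(
    intervals: Sequence[GenomicInterval],
    annotation: Annotation,
    which_boundary: str = "5ss",
    window: int = 50,
) -> MetageneProfile:
    """Mean coverage around exon-intron boundaries, strand-oriented.

    ``intervals`` may be raw reads or peaks. ``which_boundary="5ss"`` anchors
    at the exon 3' end / intron start (position 0 = first intronic base);
    ``"3ss"`` anchors at the intron 3' end / exon start (position 0 = last
    intronic base). Identical boundaries shared by several transcripts are
    counted once. Coverage is summed over boundaries and divided by the number
    of boundaries.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if which_boundary not in ("5ss", "3ss"):
        raise ValueError("which_boundary must be '5ss' or '3ss'")

    boundaries: set[tuple[str, str, int, int]] = set()  # (chrom, strand, B, direction)
    for t in annotation.transcripts():
        for intron in t.introns:
            if which_boundary == "5ss":
                # first intronic base in transcript orientation
                b = intron.start if t.strand == "+" else intron.end - 1
            else:
                # last intronic base in transcript orientation
                b = intron.end - 1 if t.strand == "+" else intron.start
            direction = 1 if t.strand == "+" else -1
            boundaries.add((t.chrom, t.strand, b, direction))
    if not boundaries:
        raise ValueError("annotation has no boundaries of the requested kind")

    # index interval endpoints per (chrom, strand) for vectorized coverage
    groups: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        groups.setdefault((iv.chrom, iv.strand), []).append(iv)
    endpoint_index = {}
    for key, ivs in groups.items():
        endpoint_index[key] = (
            np.sort(np.array([i.start for i in ivs])),
            np.sort(np.array([i.end for i in ivs])),
        )

    rel = np.arange(-window, window + 1)
    total = np.zeros(2 * window + 1, dtype=float)
    for chrom, strand, b, direction in boundaries:
        idx = endpoint_index.get((chrom, strand))
        if idx is None:
            continue
        starts, ends = idx
        pos = b + direction * rel
        cov = np.searchsorted(starts, pos, side="right") - np.searchsorted(
            ends, pos, side="right"
        )
        total += cov
    n = len(boundaries)
    return MetageneProfile(rel, total / n, n)


def biotype_distribution(
    ip_reads: ReadSet,
    neg_reads: ReadSet,
    input_reads: ReadSet,
    annotation: Annotation,
    fold: float = 1.5,
    input_fold: float = 1.5,
    biotype_map: dict | None = None,
) -> pd.DataFrame:
    """Normalized IP read totals per biotype bucket under four gating regimes.

    Per-gene read counts (a read counts for every same-strand gene body it
    overlaps) are normalized per million mapped reads within each sample. A
    gene passes the NEG gate iff normalized IP >= ``fold`` x normalized NEG,
    and the INPUT gate iff normalized IP >= ``input_fold`` x normalized INPUT
    (boundary equality passes). Returns a DataFrame indexed by biotype bucket
    with columns ``all, neg_gated, input_gated, both`` holding summed
    normalized IP reads.
    """
    for rs in (ip_reads, neg_reads, input_reads):
        if rs.total() == 0:
            raise ValueError(f"sample {rs.label!r} has zero mapped reads; normalization undefined")
    ip_norm_f = 1e6 / ip_reads.total()
    neg_norm_f = 1e6 / neg_reads.total()
    inp_norm_f = 1e6 / input_reads.total()

    data = {c: {b: 0.0 for b in BIOTYPE_BUCKETS} for c in ("all", "neg_gated", "input_gated", "both")}
    for gene in annotation.genes.values():
        sp = gene.span
        ip = ip_reads.count_overlapping(sp.chrom, sp.start, sp.end, sp.strand) * ip_norm_f
        if ip == 0:
            continue
        neg = neg_reads.count_overlapping(sp.chrom, sp.start, sp.end, sp.strand) * neg_norm_f
        inp = input_reads.count_overlapping(sp.chrom, sp.start, sp.end, sp.strand) * inp_norm_f
        bucket = aggregate_biotype(gene.biotype, biotype_map)
        pass_neg = ip >= fold * neg
        pass_inp = ip >= input_fold * inp
        data["all"][bucket] += ip
        if pass_neg:
            data["neg_gated"][bucket] += ip
        if pass_inp:
            data["input_gated"][bucket] += ip
        if pass_neg and pass_inp:
            data["both"][bucket] += ip
    return pd.DataFrame(data, index=list(BIOTYPE_BUCKETS))
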