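"""Core genomic data model: intervals, transcripts, genes and annotation.

All internal coordinates are 0-based half-open, genomic (left < right
regardless of strand). Conversion to/from the 1-based closed GTF convention
happens only inside :func:`read_annotation` / :func:`write_gtf`.

Transcript orientation ("first exon", "5' end") is strand-aware: on the minus
strand the first exon is the genomically rightmost one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: Default mapping of raw annotation biotypes to the aggregated buckets used
#: in read-distribution summaries. Anything not matched falls into "other";
#: biotypes containing the substring "pseudogene" fall into "pseudogene".
DEFAULT_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lincRNA": "lincRNA",
    "lncRNA": "lincRNA",
    "antisense": "antisense",
    "snoRNA": "short_noncoding",
    "snRNA": "short_noncoding",
    "miRNA": "short_noncoding",
    "misc_RNA": "short_noncoding",
    "rRNA": "short_noncoding",
    "scaRNA": "short_noncoding",
    "sRNA": "short_noncoding",
    "short_noncoding": "short_noncoding",
    "pseudogene": "pseudogene",
    "other": "other",
}

BIOTYPE_BUCKETS = (
    "protein_coding",
    "lincRNA",
    "antisense",
    "short_noncoding",
    "pseudogene",
    "other",
)


def aggregate_biotype(biotype: str, mapping: dict | None = None) -> str:
    """Map a raw biotype string to its aggregated bucket."""
    mapping = DEFAULT_BIOTYPE_MAP if mapping is None else mapping
    if biotype in mapping:
        return mapping[biotype]
    if "pseudogene" in biotype:
        return "pseudogene"
    return "other"


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_len(self, start: int, end: int) -> int:
        """Number of bases shared with [start, end) on the same chromosome."""
        return max(0, min(self.end, end) - max(self.start, start))


def _check_exons(exons: Sequence[GenomicInterval], tid: str) -> None:
    if not exons:
        raise AnnotationError(f"transcript {tid} has no exons")
    chrom, strand = exons[0].chrom, exons[0].strand
    for e in exons:
        if e.chrom != chrom:
            raise AnnotationError(f"transcript {tid}: exons on multiple chromosomes")
        if e.strand != strand:
            raise AnnotationError(f"transcript {tid}: exon on mismatched strand")
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise AnnotationError(f"transcript {tid}: overlapping/unsorted exons")


@dataclass
class Transcript:
    """A transcript model: ordered exons plus an optional CDS span.

    ``exons`` are stored genomically sorted; use :meth:`exons_5to3` for
    transcript orientation. ``cds_start``/``cds_end`` are genomic (left/right)
    bounds of the coding region; transcripts without a CDS are treated as
    non-coding for feature labelling.
    """

    id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        _check_exons(self.exons, self.id)
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"transcript {self.id}: partial CDS bounds")
        if self.cds_start is not None:
            if not (self.cds_start < self.cds_end):
                raise AnnotationError(f"transcript {self.id}: empty CDS")
            if self.cds_start < self.exons[0].start or self.cds_end > self.exons[-1].end:
                raise AnnotationError(f"transcript {self.id}: CDS outside exon span")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, genomically sorted."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    def exons_5to3(self) -> list[GenomicInterval]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns_5to3(self) -> list[GenomicInterval]:
        ii = self.introns
        return ii if self.strand == "+" else ii[::-1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None


@dataclass
class Gene:
    id: str
    transcripts: list[Transcript]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.id} has no transcripts")
        chrom = self.transcripts[0].chrom
        strand = self.transcripts[0].strand
        for t in self.transcripts:
            if t.gene_id != self.id:
                raise AnnotationError(f"gene {self.id}: transcript {t.id} has gene_id {t.gene_id}")
            if t.chrom != chrom or t.strand != strand:
                raise AnnotationError(f"gene {self.id}: transcripts disagree on chrom/strand")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.start for t in self.transcripts)
        end = max(t.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


class Annotation:
    """Gene set with a per-chromosome interval index for overlap queries."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.id in self.genes:
                raise AnnotationError(f"duplicate gene id {g.id}")
            self.genes[g.id] = g
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            sp = g.span
            tree.addi(sp.start, sp.end, g.id)

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts(self) -> Iterator[Transcript]:
        for g in self.genes.values():
            yield from g.transcripts

    def transcript_index(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts()}

    def overlapping_genes(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[Gene]:
        """Genes whose spans intersect [start, end); optionally strand-matched."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.span.start, g.id))

    def overlapping_transcripts(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[Transcript]:
        out = []
        for g in self.overlapping_genes(chrom, start, end, strand):
            for t in g.transcripts:
                if t.start < end and start < t.end:
                    out.append(t)
        return out


# ---------------------------------------------------------------------------
# Feature derivation


def derive_features(t: Transcript) -> list[tuple[GenomicInterval, str]]:
    """Partition a transcript span into labelled feature spans.

    Returns genomically sorted ``(interval, label)`` pairs with labels among
    ``{"five_prime_utr", "cds", "three_prime_utr", "exon", "intron"}``. Coding
    transcripts have their exons split at the CDS bounds; non-coding
    transcripts yield plain ``exon``/``intron`` spans. The returned spans
    partition ``t.span`` exactly.
    """
    out: list[tuple[GenomicInterval, str]] = []
    if not t.is_coding:
        for e in t.exons:
            out.append((e, "exon"))
    else:
        cs, ce = t.cds_start, t.cds_end
        left_label = "five_prime_utr" if t.strand == "+" else "three_prime_utr"
        right_label = "three_prime_utr" if t.strand == "+" else "five_prime_utr"
        for e in t.exons:
            pieces = []
            if e.start < cs:
                pieces.append((e.start, min(e.end, cs), left_label))
            if e.start < ce and e.end > cs:
                pieces.append((max(e.start, cs), min(e.end, ce), "cds"))
            if e.end > ce:
                pieces.append((max(e.start, ce), e.end, right_label))
            for s, x, lab in pieces:
                out.append((GenomicInterval(t.chrom, s, x, t.strand), lab))
    for i in t.introns:
        out.append((i, "intron"))
    out.sort(key=lambda p: p[0].start)
    return out


# ---------------------------------------------------------------------------
# GTF I/O

_GTF_BIOTYPE_KEYS = ("gene_biotype", "transcript_biotype", "gene_type", "transcript_type")


def _attr(feature, key):
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def _biotype_of(feature) -> str | None:
    for k in _GTF_BIOTYPE_KEYS:
        v = _attr(feature, k)
        if v:
            return v
    return None


def read_annotation(path: str | Path) -> Annotation:
    """Read an Ensembl-dialect GTF into an :class:`Annotation`.

    GTF 1-based closed coordinates are converted to 0-based half-open. Exons
    are grouped per ``transcript_id`` and sorted. Transcripts that have exon
    rows but no ``transcript`` row are synthesised from the exon union (a
    warning is logged); likewise genes missing a ``gene`` row.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, dict] = {}
    gene_meta: dict[str, dict] = {}
    tx_gene: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
            except Exception as exc:  # malformed row
                raise AnnotationError(f"{path}:{lineno}: cannot parse GTF line: {exc}")
            ftype = f.featuretype
            if ftype not in ("gene", "transcript", "exon", "CDS"):
                continue
            gid = _attr(f, "gene_id")
            if gid is None:
                raise AnnotationError(f"{path}:{lineno}: missing gene_id attribute")
            if ftype == "gene":
                gene_meta[gid] = {"biotype": _biotype_of(f)}
                continue
            tid = _attr(f, "transcript_id")
            if tid is None:
                raise AnnotationError(f"{path}:{lineno}: missing transcript_id attribute")
            tx_gene[tid] = gid
            if ftype == "transcript":
                tx_meta[tid] = {"biotype": _biotype_of(f)}
            elif ftype == "exon":
                iv = GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
                exons.setdefault(tid, []).append(iv)
                tx_meta.setdefault(tid, {}).setdefault("biotype", _biotype_of(f))
            elif ftype == "CDS":
                cds.setdefault(tid, []).append((f.start - 1, f.end))

    transcripts: dict[str, list[Transcript]] = {}
    for tid, exs in exons.items():
        meta = tx_meta.get(tid)
        if meta is None or "synth" in meta:
            logger.warning("transcript %s has exons but no transcript record; synthesized", tid)
        if tid not in tx_meta or not tx_meta[tid]:
            tx_meta[tid] = {"biotype": None}
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        gid = tx_gene[tid]
        biotype = tx_meta[tid].get("biotype") or gene_meta.get(gid, {}).get("biotype") or "protein_coding"
        t = Transcript(tid, gid, exs, cds_start, cds_end, biotype)
        transcripts.setdefault(gid, []).append(t)

    genes = []
    for gid, txs in transcripts.items():
        if gid not in gene_meta:
            logger.warning("gene %s has no gene record; synthesized from transcripts", gid)
        biotype = gene_meta.get(gid, {}).get("biotype") or txs[0].biotype
        genes.append(Gene(gid, sorted(txs, key=lambda t: t.id), biotype))
    return Annotation(genes)


def write_gtf(annotation: Annotation, path: str | Path) -> None:
    """Write an annotation as Ensembl-dialect GTF (1-based closed coords)."""
    with open(path, "w") as fh:
        for g in sorted(annotation.genes.values(), key=lambda g: (g.chrom, g.span.start)):
            sp = g.span

            def row(ftype, start, end, attrs):
                astr = " ".join(f'{k} "{v}";' for k, v in attrs)
                fh.write(
                    f"{g.chrom}\tclipsplice\t{ftype}\t{start + 1}\t{end}\t.\t{g.strand}\t.\t{astr}\n"
                )

            row("gene", sp.start, sp.end, [("gene_id", g.id), ("gene_biotype", g.biotype)])
            for t in g.transcripts:
                attrs = [
                    ("gene_id", g.id),
                    ("transcript_id", t.id),
                    ("gene_biotype", g.biotype),
                    ("transcript_biotype", t.biotype),
                ]
                row("transcript", t.start, t.end, attrs)
                for e in t.exons:
                    row("exon", e.start, e.end, attrs)
                if t.is_coding:
                    for e in t.exons:
                        s = max(e.start, t.cds_start)
                        x = min(e.end, t.cds_end)
                        if s < x:
                            row("CDS", s, x, attrs)


# ---------------------------------------------------------------------------
# BED I/O

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path, strand_policy: str = "require") -> list[GenomicInterval]:
    """Read a BED6 file into stranded intervals.

    ``strand_policy`` controls records with strand ``"."``: ``"require"``
    rejects them with a warning (CLIP inputs are strand-specific), while
    ``"+"``/``"-"`` substitutes that default strand. Records with
    ``start >= end`` are always rejected with a warning.
    """
    if strand_policy not in ("require", "+", "-"):
        raise ValueError(f"invalid strand_policy {strand_policy!r}")
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=BED6_COLUMNS, usecols=range(6), dtype={0: str},
    )
    out = []
    for rec in df.itertuples(index=False):
        if rec.start >= rec.end:
            logger.warning("rejecting BED record with start >= end: %s", tuple(rec))
            continue
        strand = rec.strand
        if strand not in STRANDS:
            if strand_policy == "require":
                logger.warning("rejecting unstranded BED record: %s", tuple(rec))
                continue
            strand = strand_policy
        out.append(GenomicInterval(str(rec.chrom), int(rec.start), int(rec.end), strand))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED6 (name/score default to "." and 0)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
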