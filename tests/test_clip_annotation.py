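"""Peak annotation: categories, exon ordinals, junctions, metagene, biotypes."""

import numpy as np
import pytest

from clipsplice.clip_annotation import (
    DEFAULT_PRECEDENCE,
    annotate_peaks,
    assign_category,
    biotype_distribution,
    classify_exon_position,
    flag_junction_spanning,
    metagene_profile,
    representative_transcript,
)
from clipsplice.clip_peaks import ReadSet
from clipsplice.genome_model import Annotation, GenomicInterval, derive_features

from conftest import make_gene, make_tx, random_transcript


def iv(s, e, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, s, e, strand)


@pytest.fixture
def simple_annotation():
    # + strand coding gene: exons (0,100),(200,300),(400,500), CDS 50..450
    g = make_gene("gA", [[(0, 100), (200, 300), (400, 500)]], cds=(50, 450))
    return Annotation([g])


def test_assign_category_intron_and_intergenic(simple_annotation):
    assert assign_category(iv(120, 160), simple_annotation).category == "intron"
    assert assign_category(iv(900, 950), simple_annotation).category == "intergenic"
    # opposite strand does not hit the gene
    assert assign_category(iv(120, 160, "-"), simple_annotation).category == "intergenic"


def test_assign_category_dominant_overlap(simple_annotation):
    # 30 nt in exon 2, 10 nt in the upstream intron -> exon
    pa = assign_category(iv(190, 230), simple_annotation)
    assert pa.category == "exon"
    assert pa.gene_id == "gA"


def test_assign_category_utr(simple_annotation):
    assert assign_category(iv(0, 40), simple_annotation).category == "5utr"
    assert assign_category(iv(460, 500), simple_annotation).category == "3utr"


def _oracle_category(peak, transcripts, precedence=DEFAULT_PRECEDENCE):
    """Brute-force per-base category oracle with the stated precedence."""
    rank = {lab: i for i, lab in enumerate(precedence)}
    best = None
    for t in transcripts:
        if t.strand != peak.strand or t.chrom != peak.chrom:
            continue
        counts = {}
        for pos in range(peak.start, peak.end):
            for fiv, lab in derive_features(t):
                if fiv.start <= pos < fiv.end:
                    counts[lab] = counts.get(lab, 0) + 1
        if not counts:
            continue
        lab, ov = max(counts.items(), key=lambda kv: (kv[1], -rank[kv[0]]))
        key = (ov, -rank[lab])
        if best is None or key > best[0]:
            best = (key, lab)
    if best is None:
        return "intergenic"
    return {"cds": "exon", "exon": "exon", "five_prime_utr": "5utr",
            "three_prime_utr": "3utr", "intron": "intron"}[best[1]]


def test_assign_category_matches_brute_force(rng):
    genes = [
        make_gene(f"g{i}", [[(e.start, e.end) for e in t.exons]], strand=t.strand,
                  cds=(t.cds_start, t.cds_end) if t.is_coding else None)
        for i, t in ((i, random_transcript(rng, f"t{i}", coding=bool(i % 2)))
                     for i in range(25))
    ]
    ann = Annotation(genes)
    txs = [t for g in genes for t in g.transcripts]
    hi = max(t.end for t in txs) + 50
    for _ in range(100):
        s = int(rng.integers(0, hi))
        peak = iv(s, s + int(rng.integers(5, 120)), "+" if rng.random() < 0.5 else "-")
        assert assign_category(peak, ann).category == _oracle_category(peak, txs)


def test_exon_position_classes():
    g = make_gene("g", [[(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)]])
    assert classify_exon_position(iv(10, 50), g) == "first_exon"
    assert classify_exon_position(iv(420, 460), g) == "mid_exon"
    assert classify_exon_position(iv(850, 890), g) == "last_exon"
    assert classify_exon_position(iv(120, 150), g) == "first_intron"
    assert classify_exon_position(iv(320, 350), g) == "mid_intron"
    assert classify_exon_position(iv(720, 750), g) == "last_intron"


def test_exon_position_minus_strand_inverts():
    """Leftmost genomic exon of a minus-strand gene is the LAST exon."""
    g = make_gene("g", [[(0, 100), (200, 300), (400, 500)]], strand="-")
    assert classify_exon_position(iv(10, 50, "-"), g) == "last_exon"
    assert classify_exon_position(iv(420, 460, "-"), g) == "first_exon"
    assert classify_exon_position(iv(120, 150, "-"), g) == "last_intron"


def test_exon_position_requires_three_exons():
    g = make_gene("g", [[(0, 100), (200, 300)]])
    assert classify_exon_position(iv(10, 50), g) is None


def test_representative_transcript_rule():
    g = make_gene("g", [[(0, 100), (200, 300)], [(0, 100), (200, 300), (400, 500)]])
    assert representative_transcript(g).id == "g.t2"


def test_junction_flag(simple_annotation):
    flags, frac = flag_junction_spanning([iv(95, 105), iv(10, 90)], simple_annotation)
    assert flags == [True, False]
    assert frac == 0.5


def test_annotate_peaks_combines(simple_annotation):
    (pa,) = annotate_peaks([iv(95, 105)], simple_annotation)
    assert pa.junction_spanning and pa.category in ("exon", "intron")
    assert pa.exon_position == "first_exon"


def _mirror_interval(ivl, L):
    return GenomicInterval(ivl.chrom, L - ivl.end, L - ivl.start,
                           "+" if ivl.strand == "-" else "-")


def test_strand_inversion_leaves_summaries_unchanged(rng):
    """Mirroring the whole fixture to the opposite strand preserves all
    category and ordinal summaries."""
    genes = []
    for i in range(10):
        t = random_transcript(rng, f"t{i}", coding=True, max_exons=5)
        genes.append(make_gene(f"g{i}", [[(e.start, e.end) for e in t.exons]],
                               strand=t.strand,
                               cds=(t.cds_start, t.cds_end) if t.is_coding else None))
    ann = Annotation(genes)
    L = max(g.span.end for g in genes) + 100
    peaks = []
    for _ in range(60):
        s = int(rng.integers(0, L - 130))
        peaks.append(iv(s, s + int(rng.integers(10, 120)),
                        "+" if rng.random() < 0.5 else "-"))

    mirrored_genes = []
    for g in genes:
        t = g.transcripts[0]
        exons = sorted((L - e.end, L - e.start) for e in t.exons)
        cds = (L - t.cds_end, L - t.cds_start) if t.is_coding else None
        mirrored_genes.append(make_gene(g.id, [exons],
                                        strand="+" if g.strand == "-" else "-", cds=cds))
    ann_m = Annotation(mirrored_genes)
    peaks_m = [_mirror_interval(p, L) for p in peaks]

    def summarize(annos):
        cats = sorted(a.category for a in annos)
        ords = sorted(a.exon_position or "NA" for a in annos)
        juncs = sorted(a.junction_spanning for a in annos)
        return cats, ords, juncs

    assert summarize(annotate_peaks(peaks, ann)) == summarize(annotate_peaks(peaks_m, ann_m))


# ---------------------------------------------------------------------------
# metagene


def test_metagene_no_reads_and_single_read(simple_annotation):
    prof = metagene_profile([], simple_annotation, "5ss", window=20)
    assert prof.mean_coverage.tolist() == [0.0] * 41
    # single boundary-straddling read [-5,+5) around the boundary at 100
    g = make_gene("g1", [[(0, 100), (200, 300)]])
    ann1 = Annotation([g])
    prof = metagene_profile([iv(95, 105)], ann1, "5ss", window=10)
    rel = prof.positions.tolist()
    cov = prof.mean_coverage
    covered = {rel[i] for i in range(len(rel)) if cov[i] == 1.0}
    assert covered == set(range(-5, 5))
    assert prof.n_boundaries == 1


def test_metagene_window_validation(simple_annotation):
    with pytest.raises(ValueError):
        metagene_profile([], simple_annotation, "5ss", window=0)


def test_metagene_peak_at_boundary_minus_strand():
    """Reads planted symmetrically around a minus-strand donor boundary give a
    profile maximal within 2 nt of position 0."""
    g = make_gene("g", [[(0, 300), (500, 800)]], strand="-")
    ann = Annotation([g])
    # 5'SS of the minus-strand transcript: first intronic base = 499
    rng = np.random.default_rng(7)
    reads = []
    for _ in range(300):
        c = 499 + int(round(rng.normal(0, 4)))
        w = int(rng.integers(20, 40))
        reads.append(iv(max(0, c - w // 2), max(0, c - w // 2) + w, "-"))
    prof = metagene_profile(reads, ann, "5ss", window=50)
    argmax = prof.positions[int(np.argmax(prof.mean_coverage))]
    assert abs(argmax) <= 2


# ---------------------------------------------------------------------------
# biotype distribution


def _one_gene_ann(biotype="protein_coding", strand="+"):
    return Annotation([make_gene("g", [[(0, 500)]], strand=strand, biotype=biotype)])


def test_biotype_all_reads_one_gene():
    ann = _one_gene_ann()
    ip = ReadSet("IP", [iv(10, 50) for _ in range(20)])
    neg = ReadSet("NEG", [iv(5000, 5040)])  # outside the gene: count 0
    inp = ReadSet("INPUT", [iv(5000, 5040)])
    table = biotype_distribution(ip, neg, inp, ann)
    for col in table.columns:
        assert table.loc["protein_coding", col] == pytest.approx(1e6)
        assert table[col].sum() == pytest.approx(1e6)


def test_biotype_boundary_equality_passes():
    """Normalized IP exactly 1.5x normalized NEG passes the gate."""
    ann = _one_gene_ann()
    ip = ReadSet("IP", [iv(10, 50) for _ in range(3)])  # all reads in gene
    neg = ReadSet("NEG", [iv(10, 50), iv(10, 50), iv(600, 640)])  # 2 of 3 in gene
    inp = ReadSet("INPUT", [iv(600, 640)])
    table = biotype_distribution(ip, neg, inp, ann)
    # normalized IP = 1e6, normalized NEG = 2/3*1e6 -> 1e6 >= 1.5 * 0.666e6
    assert table.loc["protein_coding", "neg_gated"] == pytest.approx(1e6)


def test_biotype_zero_sample_errors():
    ann = _one_gene_ann()
    with pytest.raises(ValueError):
        biotype_distribution(ReadSet("IP", []), ReadSet("NEG", [iv(0, 10)]),
                             ReadSet("INPUT", [iv(0, 10)]), ann)


def test_biotype_gating_matches_oracle(rng):
    """Mixed 10-gene fixture: regime totals equal a gate-and-sum oracle, and
    gated totals never exceed ungated ones."""
    biotypes = ["protein_coding", "lincRNA", "antisense", "snoRNA", "processed_pseudogene"]
    genes = []
    for i in range(10):
        s = i * 1000
        genes.append(make_gene(f"g{i}", [[(s, s + 600)]], biotype=biotypes[i % 5]))
    ann = Annotation(genes)

    def sample(label, per_gene):
        reads = []
        for i, n in enumerate(per_gene):
            reads += [iv(i * 1000 + 10, i * 1000 + 50) for _ in range(n)]
        return ReadSet(label, reads)

    ip = sample("IP", rng.integers(1, 30, size=10))
    neg = sample("NEG", rng.integers(0, 20, size=10))
    inp = sample("INPUT", rng.integers(0, 20, size=10))
    table = biotype_distribution(ip, neg, inp, ann)

    from clipsplice.genome_model import aggregate_biotype
    expected = {c: {} for c in table.columns}
    for i, g in enumerate(genes):
        ipc = ip.count_overlapping("chr1", i * 1000, i * 1000 + 600, "+") * 1e6 / ip.total()
        ngc = neg.count_overlapping("chr1", i * 1000, i * 1000 + 600, "+") * 1e6 / neg.total()
        inc = inp.count_overlapping("chr1", i * 1000, i * 1000 + 600, "+") * 1e6 / inp.total()
        bucket = aggregate_biotype(g.biotype)
        for col, ok in (
            ("all", True),
            ("neg_gated", ipc >= 1.5 * ngc),
            ("input_gated", ipc >= 1.5 * inc),
            ("both", ipc >= 1.5 * ngc and ipc >= 1.5 * inc),
        ):
            if ok:
                expected[col][bucket] = expected[col].get(bucket, 0.0) + ipc
    for col in table.columns:
        for bucket in table.index:
            assert table.loc[bucket, col] == pytest.approx(expected[col].get(bucket, 0.0))
        assert (table[col] <= table["all"] + 1e-9).all()
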