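"""Synthetic annotation, CLIP read sets and expression tables with ground truth.

The generator emulates the statistical structure of a strand-specific CLIP
experiment plus knockdown RNA-seq so that every downstream stage is testable
without real sequencing data:

* an annotation of single- and multi-isoform genes (multi-isoform genes are
  created for each planted alternative-splicing event);
* CLIP read sets for several IP replicates, a negative-control IP and a
  size-matched input: planted peaks at exon-intron boundaries or within
  exons over Poisson background on gene bodies, plus diffuse "sticky"
  nonspecific regions (a callable core surrounded by a broad low-density
  read plateau) that a specificity ratio filter should remove; control and
  input carry background only;
* replicate TPM tables for a control and two simulated knockdowns with
  planted up/down-regulated genes partially shared between the knockdowns,
  planted PSI shifts realized by moving isoform TPM shares, and gene/
  transcript statistic tables (signed natural-log effect b, BH-adjusted q)
  from a two-sample t-test on log TPM.

One RNG stream per generator, derived from the master seed by fixed spawn
keys, so adding peaks never perturbs the expression draws. A fixed seed
gives bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clip_peaks import ReadSet
from .genome_model import Annotation, Gene, GenomicInterval, Transcript, write_bed, write_gtf

_AS_TYPES = ("SE", "A5", "A3", "MX", "RI", "AF", "AL")


@dataclass
class SimulationConfig:
    """Ground-truth simulation parameters.

    Rates are per replicate; ``background_rate`` and friends are expected
    reads per nucleotide of gene body (Poisson). ``lfc_effect`` and
    ``tpm_noise_sd`` are on the natural-log scale, positive effect = up in
    knockdown. ``peak_read_rate`` is the expected number of reads per planted
    peak per IP replicate.
    """

    seed: int = 0
    # annotation
    n_genes: int = 200
    exon_count_range: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (80, 300)
    intron_length_range: tuple[int, int] = (200, 1500)
    intergenic_gap_range: tuple[int, int] = (800, 3000)
    biotype_proportions: dict = field(
        default_factory=lambda: {
            "protein_coding": 0.75,
            "lincRNA": 0.08,
            "antisense": 0.05,
            "short_noncoding": 0.05,
            "pseudogene": 0.04,
            "other": 0.03,
        }
    )
    # CLIP
    n_planted_peaks: int = 200
    junction_spanning_fraction: float = 0.5
    peak_read_rate: float = 30.0
    background_rate: float = 0.01
    control_rate: float | None = None  # defaults to background_rate
    input_rate: float | None = None  # defaults to background_rate
    control_leakage: float = 0.0
    n_ip_replicates: int = 5
    n_nonspecific_regions: int = 60
    nonspecific_core_rate: float = 15.0
    nonspecific_halfwidth: int = 150
    nonspecific_density: float = 0.08
    read_length_range: tuple[int, int] = (30, 60)
    peak_jitter_sd: float = 5.0
    # expression
    n_expr_replicates: int = 3
    de_fraction_up: float = 0.15
    de_fraction_down: float = 0.15
    lfc_effect: float = 1.5
    shared_up_fraction: float = 0.25
    shared_down_fraction: float = 0.25
    planted_as_events: tuple = tuple([("SE", 0.4)] * 8 + [("AF", 0.4)] * 8)
    as_gene_total_tpm: float = 20.0
    tpm_noise_sd: float = 0.15
    log_tpm_mean: float = 1.5
    log_tpm_sd: float = 1.0

    def validate(self) -> None:
        for name in (
            "junction_spanning_fraction",
            "de_fraction_up",
            "de_fraction_down",
            "shared_up_fraction",
            "shared_down_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "peak_read_rate", "background_rate", "tpm_noise_sd",
            "nonspecific_core_rate", "nonspecific_density", "control_leakage",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        props = self.biotype_proportions
        if abs(sum(props.values()) - 1.0) > 1e-6:
            raise ValueError("biotype proportions must sum to 1")
        if len(self.planted_as_events) > self.n_genes:
            raise ValueError(
                f"{len(self.planted_as_events)} planted AS events need at least "
                f"that many genes (n_genes={self.n_genes})"
            )
        for etype, dpsi in self.planted_as_events:
            if etype not in _AS_TYPES:
                raise ValueError(f"unknown AS event type {etype}")
            if not -0.9 <= dpsi <= 0.9:
                raise ValueError(f"planted dPSI {dpsi} out of range")


@dataclass
class TruthTables:
    """Ground truth emitted alongside the simulated data."""

    peaks: list[dict] = field(default_factory=list)
    nonspecific: list[dict] = field(default_factory=list)
    as_events: list[dict] = field(default_factory=list)
    de: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "peaks": self.peaks,
            "nonspecific": self.nonspecific,
            "as_events": self.as_events,
            "de": {
                k: {d: sorted(v[d]) for d in ("up", "down")} for k, v in self.de.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SimulatedClip:
    ip_replicates: list[ReadSet]
    negative: ReadSet
    sm_input: ReadSet


@dataclass
class SimulatedExpression:
    tpm: pd.DataFrame  # transcripts x replicate columns
    columns: dict[str, list[str]]  # condition -> column names
    gene_stats: dict[str, pd.DataFrame]  # knockdown -> (gene_id, b, qval)
    transcript_stats: dict[str, pd.DataFrame]
    tx_gene: dict[str, str]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Annotation


def _psi_levels(dpsi: float) -> tuple[float, float]:
    """Control/treated PSI pair centered on 0.5 realizing the planted shift."""
    lo = np.clip(0.5 - dpsi / 2.0, 0.02, 0.98)
    hi = np.clip(lo + dpsi, 0.02, 0.98)
    return float(lo), float(hi)


def _alt_isoform(
    exons: list[tuple[int, int]], etype: str, strand: str, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Second isoform realizing one planted local event on the base chain."""
    n = len(exons)
    j = n // 2  # internal exon manipulated
    alt = [list(e) for e in exons]
    if etype == "SE":
        del alt[j]
    elif etype == "RI":
        alt[j][1] = alt[j + 1][1]
        del alt[j + 1]
    elif etype == "A5":
        delta = int(rng.integers(30, 80))
        if strand == "+":
            alt[j][1] += delta  # donor shift into the downstream intron
        else:
            alt[j][0] -= delta
    elif etype == "A3":
        delta = int(rng.integers(30, 80))
        if strand == "+":
            alt[j + 1][0] -= delta  # acceptor shift into the upstream intron
        else:
            alt[j - 1][1] += delta
    elif etype == "MX":
        gap = 50
        width = 60
        s = exons[j][1] + gap
        alt[j] = [s, s + width]
    elif etype == "AF":
        width = int(rng.integers(80, 150))
        if strand == "+":
            s = exons[0][0] - 400
            alt[0] = [s, s + width]
        else:
            s = exons[-1][1] + 300
            alt[-1] = [s, s + width]
    elif etype == "AL":
        width = int(rng.integers(80, 150))
        if strand == "+":
            s = exons[-1][1] + 300
            alt[-1] = [s, s + width]
        else:
            s = exons[0][0] - 400
            alt[0] = [s, s + width]
    else:  # pragma: no cover
        raise ValueError(etype)
    return [tuple(e) for e in alt]


def _cds_bounds(exons: list[tuple[int, int]]) -> tuple[int, int] | None:
    first, last = exons[0], exons[-1]
    cs = first[0] + (first[1] - first[0]) // 2
    ce = last[1] - (last[1] - last[0]) // 2
    return (cs, ce) if cs < ce else None


def simulate_annotation(config: SimulationConfig) -> tuple[Annotation, TruthTables]:
    """Generate a gene annotation with multi-isoform genes for planted events."""
    config.validate()
    rng = _rng(config.seed, 0)
    truth = TruthTables()
    chrom = "chr1"
    cursor = 1000
    genes: list[Gene] = []
    buckets = list(config.biotype_proportions.keys())
    probs = np.array([config.biotype_proportions[b] for b in buckets])

    for gi in range(config.n_genes):
        gid = f"G{gi:04d}"
        as_spec = config.planted_as_events[gi] if gi < len(config.planted_as_events) else None
        strand = "+" if rng.random() < 0.5 else "-"
        lo, hi = config.exon_count_range
        n_exons = int(rng.integers(lo, hi + 1))
        if as_spec is not None:
            n_exons = max(n_exons, 4)
        exon_lens = rng.integers(*config.exon_length_range, size=n_exons)
        intron_lens = rng.integers(*config.intron_length_range, size=max(n_exons - 1, 0))
        start = cursor + int(rng.integers(*config.intergenic_gap_range))
        exons: list[tuple[int, int]] = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos = exons[-1][1] + (int(intron_lens[k]) if k < n_exons - 1 else 0)

        biotype = (
            "protein_coding" if as_spec is not None else str(rng.choice(buckets, p=probs))
        )
        coding = biotype == "protein_coding"

        def build_tx(tid: str, chain: list[tuple[int, int]]) -> Transcript:
            ivs = [GenomicInterval(chrom, s, e, strand) for s, e in sorted(chain)]
            cds = _cds_bounds(sorted(chain)) if coding else None
            return Transcript(
                tid, gid, ivs,
                cds_start=cds[0] if cds else None,
                cds_end=cds[1] if cds else None,
                biotype=biotype,
            )

        txs = [build_tx(f"{gid}.t1", exons)]
        if as_spec is not None:
            etype, dpsi = as_spec
            alt = _alt_isoform(exons, etype, strand, rng)
            txs.append(build_tx(f"{gid}.t2", alt))
            psi_c, psi_t = _psi_levels(dpsi)
            truth.as_events.append(
                {
                    "gene_id": gid,
                    "type": etype,
                    # inclusion by convention = the base isoform t1 except for
                    # RI, where t2 retains the intron
                    "inclusion_tx": f"{gid}.t2" if etype == "RI" else f"{gid}.t1",
                    "exclusion_tx": f"{gid}.t1" if etype == "RI" else f"{gid}.t2",
                    "dpsi": float(dpsi),
                    "psi_control": psi_c,
                    "psi_treated": psi_t,
                }
            )
        genes.append(Gene(gid, txs, biotype))
        cursor = max(t.end for t in txs)
    return Annotation(genes), truth


# ---------------------------------------------------------------------------
# CLIP reads


def _read_at(
    rng: np.random.Generator, chrom: str, strand: str, center: int, cfg: SimulationConfig
) -> GenomicInterval:
    width = int(rng.integers(*cfg.read_length_range))
    start = max(0, center - width // 2)
    return GenomicInterval(chrom, start, start + width, strand)


def _background_reads(
    rng: np.random.Generator, annotation: Annotation, rate: float, cfg: SimulationConfig
) -> list[GenomicInterval]:
    out = []
    for g in annotation.genes.values():
        sp = g.span
        n = rng.poisson(rate * sp.width)
        for _ in range(n):
            c = int(rng.integers(sp.start, sp.end))
            out.append(_read_at(rng, sp.chrom, sp.strand, c, cfg))
    return out


def simulate_clip_reads(
    annotation: Annotation, truth: TruthTables, config: SimulationConfig
) -> SimulatedClip:
    """Generate IP replicate, negative-control and size-matched input reads.

    Planted peaks receive Poisson(``peak_read_rate``) reads per IP replicate,
    centered near the anchor with Gaussian jitter; junction-spanning peaks are
    anchored at an exon 3' end so the pile-up straddles the boundary.
    Nonspecific sticky regions receive a tight read core plus a broad uniform
    plateau in every IP replicate. All samples carry Poisson background
    uniform over gene bodies; the negative control and input carry background
    only (plus optional planted-peak leakage into the control).
    """
    config.validate()
    rng = _rng(config.seed, 1)
    genes = list(annotation.genes.values())

    # --- choose planted peak anchors
    junction_candidates: list[tuple[str, str, int, str]] = []  # chrom,strand,B,gene
    for g in genes:
        for t in g.transcripts:
            for intron in t.introns:
                b = intron.start if t.strand == "+" else intron.end - 1
                junction_candidates.append((t.chrom, t.strand, b, g.id))
    n_junc = int(round(config.junction_spanning_fraction * config.n_planted_peaks))
    n_junc = min(n_junc, config.n_planted_peaks)
    anchors: list[tuple[str, str, int, str, bool]] = []
    if n_junc > 0 and junction_candidates:
        idx = rng.choice(
            len(junction_candidates), size=n_junc,
            replace=len(junction_candidates) < n_junc,
        )
        for i in idx:
            c, s, b, gid = junction_candidates[int(i)]
            anchors.append((c, s, b, gid, True))
    exonic: list[tuple[str, str, int, str]] = []
    for g in genes:
        t = g.transcripts[0]
        for e in t.exons:
            if e.width > 30:
                exonic.append((e.chrom, e.strand, (e.start + e.end) // 2, g.id))
    n_body = config.n_planted_peaks - len(anchors)
    if n_body > 0 and exonic:
        idx = rng.choice(len(exonic), size=n_body, replace=len(exonic) < n_body)
        for i in idx:
            c, s, m, gid = exonic[int(i)]
            anchors.append((c, s, m, gid, False))

    truth.peaks = [
        {"chrom": c, "start": b - 20, "end": b + 20, "strand": s, "gene_id": gid, "junction": j}
        for c, s, b, gid, j in anchors
    ]

    # --- nonspecific sticky regions (gene-body positions, IP only)
    sticky: list[tuple[str, str, int]] = []
    if config.n_nonspecific_regions > 0 and genes:
        gidx = rng.choice(len(genes), size=config.n_nonspecific_regions, replace=True)
        for i in gidx:
            sp = genes[int(i)].span
            c = int(rng.integers(sp.start, sp.end))
            sticky.append((sp.chrom, sp.strand, c))
    truth.nonspecific = [
        {
            "chrom": c,
            "start": m - config.nonspecific_halfwidth,
            "end": m + config.nonspecific_halfwidth,
            "strand": s,
        }
        for c, s, m in sticky
    ]

    ctrl_rate = config.background_rate if config.control_rate is None else config.control_rate
    input_rate = config.background_rate if config.input_rate is None else config.input_rate

    ip_reps = []
    for r in range(config.n_ip_replicates):
        reads: list[GenomicInterval] = []
        for c, s, b, gid, _j in anchors:
            k = rng.poisson(config.peak_read_rate)
            for _ in range(k):
                center = b + int(round(rng.normal(0.0, config.peak_jitter_sd)))
                reads.append(_read_at(rng, c, s, center, config))
        for c, s, m in sticky:
            k = rng.poisson(config.nonspecific_core_rate)
            for _ in range(k):
                center = m + int(round(rng.normal(0.0, 6.0)))
                reads.append(_read_at(rng, c, s, center, config))
            k = rng.poisson(config.nonspecific_density * 2 * config.nonspecific_halfwidth)
            for _ in range(k):
                center = int(
                    rng.integers(m - config.nonspecific_halfwidth, m + config.nonspecific_halfwidth)
                )
                reads.append(_read_at(rng, c, s, center, config))
        reads.extend(_background_reads(rng, annotation, config.background_rate, config))
        ip_reps.append(ReadSet(f"IP_rep_{r + 1}", reads))

    neg_reads = _background_reads(rng, annotation, ctrl_rate, config)
    if config.control_leakage > 0:
        for c, s, b, gid, _j in anchors:
            k = rng.poisson(config.control_leakage * config.peak_read_rate)
            for _ in range(k):
                center = b + int(round(rng.normal(0.0, config.peak_jitter_sd)))
                neg_reads.append(_read_at(rng, c, s, center, config))
    negative = ReadSet("NEG", neg_reads)
    sm_input = ReadSet("INPUT", _background_reads(rng, annotation, input_rate, config))
    return SimulatedClip(ip_reps, negative, sm_input)


# ---------------------------------------------------------------------------
# Expression


def _bh(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def compute_stat_tables(
    tpm: pd.DataFrame,
    control_cols: Sequence[str],
    treated_cols: Sequence[str],
    tx_gene: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene- and transcript-level stats (b, q) from a replicate TPM table.

    b is the mean natural-log fold change (treated minus control); p-values
    come from a two-sample t-test on log TPM and are BH-adjusted within each
    table. Gene-level TPM is the sum of the gene's transcripts.
    """
    if len(control_cols) < 2 or len(treated_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")

    def table(values: pd.DataFrame) -> pd.DataFrame:
        la = np.log(values[list(control_cols)].to_numpy(dtype=float) + 1e-9)
        lb = np.log(values[list(treated_cols)].to_numpy(dtype=float) + 1e-9)
        b = lb.mean(axis=1) - la.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.ttest_ind(lb, la, axis=1).pvalue
        p = np.where(np.isfinite(p), p, 1.0)
        return pd.DataFrame({"id": values.index, "b": b, "pval": p, "qval": _bh(p)})

    tx_tab = table(tpm)
    tx_tab = tx_tab.rename(columns={"id": "transcript_id"})
    tx_tab["gene_id"] = tx_tab["transcript_id"].map(tx_gene)
    tx_tab = tx_tab[["transcript_id", "gene_id", "b", "pval", "qval"]]

    gene_tpm = tpm.groupby(pd.Series(tx_gene).reindex(tpm.index)).sum()
    g_tab = table(gene_tpm).rename(columns={"id": "gene_id"})
    return g_tab.reset_index(drop=True), tx_tab.reset_index(drop=True)


def simulate_expression(
    annotation: Annotation, truth: TruthTables, config: SimulationConfig
) -> SimulatedExpression:
    """Generate replicate TPM tables and stat tables for two knockdowns.

    Baseline transcript TPMs are log-normal; differentially expressed genes
    are shifted by +/-``lfc_effect`` (natural log) in the knockdown
    replicates, with ``shared_up_fraction`` of knockdown A's up genes planted
    in knockdown B as well (and likewise for down). Planted AS events are
    realized by shifting isoform TPM shares in knockdown A to hit the true
    PSI change. Each replicate column is renormalized to one million.
    """
    config.validate()
    if config.n_expr_replicates < 2:
        raise ValueError("need >= 2 replicates per condition for a variance estimate")
    rng = _rng(config.seed, 2)
    gene_ids = sorted(annotation.genes.keys())
    as_by_gene = {ev["gene_id"]: ev for ev in truth.as_events}

    # --- planted DE sets
    n_up = int(round(config.de_fraction_up * len(gene_ids)))
    n_down = int(round(config.de_fraction_down * len(gene_ids)))
    perm = list(rng.permutation(gene_ids))
    a_up, a_down = set(perm[:n_up]), set(perm[n_up:n_up + n_down])
    n_shared_up = int(round(config.shared_up_fraction * n_up))
    n_shared_down = int(round(config.shared_down_fraction * n_down))
    b_up = set(rng.choice(sorted(a_up), size=n_shared_up, replace=False)) if n_shared_up else set()
    b_down = (
        set(rng.choice(sorted(a_down), size=n_shared_down, replace=False)) if n_shared_down else set()
    )
    pool = [g for g in perm if g not in a_up and g not in a_down]
    b_up |= set(pool[: n_up - n_shared_up])
    b_down |= set(pool[n_up - n_shared_up : n_up - n_shared_up + n_down - n_shared_down])
    truth.de = {"A": {"up": a_up, "down": a_down}, "B": {"up": b_up, "down": b_down}}

    conditions = ("ctrl", "kdA", "kdB")
    columns = {c: [f"{c}_{i + 1}" for i in range(config.n_expr_replicates)] for c in conditions}

    tx_ids: list[str] = []
    tx_gene: dict[str, str] = {}
    base: dict[str, dict[str, float]] = {}  # tx -> condition -> expected TPM
    for gid in gene_ids:
        gene = annotation.genes[gid]
        ev = as_by_gene.get(gid)
        if ev is not None:
            total = config.as_gene_total_tpm
            incl, excl = ev["inclusion_tx"], ev["exclusion_tx"]
            for tx in gene.transcripts:
                tx_ids.append(tx.id)
                tx_gene[tx.id] = gid
                share_c = ev["psi_control"] if tx.id == incl else 1.0 - ev["psi_control"]
                share_t = ev["psi_treated"] if tx.id == incl else 1.0 - ev["psi_treated"]
                base[tx.id] = {
                    "ctrl": total * share_c,
                    "kdA": total * share_t,
                    "kdB": total * share_c,
                }
        else:
            for tx in gene.transcripts:
                tx_ids.append(tx.id)
                tx_gene[tx.id] = gid
                level = float(np.exp(rng.normal(config.log_tpm_mean, config.log_tpm_sd)))
                base[tx.id] = {c: level for c in conditions}

    effect = {
        ("kdA", gid): (config.lfc_effect if gid in a_up else -config.lfc_effect if gid in a_down else 0.0)
        for gid in gene_ids
    }
    effect.update(
        {
            ("kdB", gid): (
                config.lfc_effect if gid in b_up else -config.lfc_effect if gid in b_down else 0.0
            )
            for gid in gene_ids
        }
    )

    data = {}
    for cond in conditions:
        for col in columns[cond]:
            mean = np.array(
                [
                    base[tid][cond] * np.exp(effect.get((cond, tx_gene[tid]), 0.0))
                    for tid in tx_ids
                ]
            )
            noise = np.exp(rng.normal(0.0, config.tpm_noise_sd, size=len(tx_ids)))
            vals = mean * noise
            data[col] = vals * (1e6 / vals.sum())
    tpm = pd.DataFrame(data, index=tx_ids)

    gene_stats, tx_stats = {}, {}
    for kd in ("kdA", "kdB"):
        g, t = compute_stat_tables(tpm, columns["ctrl"], columns[kd], tx_gene)
        key = "A" if kd == "kdA" else "B"
        gene_stats[key], tx_stats[key] = g, t
    return SimulatedExpression(tpm, columns, gene_stats, tx_stats, tx_gene)


# ---------------------------------------------------------------------------
# File output


def save_simulation(
    outdir: str | Path,
    annotation: Annotation,
    truth: TruthTables,
    clip: SimulatedClip | None = None,
    expression: SimulatedExpression | None = None,
    config: SimulationConfig | None = None,
) -> None:
    """Write GTF, per-sample read BEDs, TPM/stat TSVs and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(annotation, outdir / "annotation.gtf")
    truth.to_json(outdir / "truth.json")
    if clip is not None:
        for rs in clip.ip_replicates + [clip.negative, clip.sm_input]:
            write_bed(rs.reads, outdir / f"reads_{rs.label}.bed")
    if expression is not None:
        expression.tpm.rename_axis("transcript_id").to_csv(outdir / "tpm.tsv", sep="\t")
        for key in expression.gene_stats:
            expression.gene_stats[key].to_csv(
                outdir / f"gene_stats_{key}.tsv", sep="\t", index=False
            )
            expression.transcript_stats[key].to_csv(
                outdir / f"transcript_stats_{key}.tsv", sep="\t", index=False
            )
    if config is not None:
        cfg = asdict(config)
        cfg["planted_as_events"] = [list(e) for e in config.planted_as_events]
        (outdir / "config.json").write_text(json.dumps(cfg, indent=1))
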