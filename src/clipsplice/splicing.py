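"""Local alternative-splicing events, PSI quantification and dPSI calling.

Events are generated by pairwise comparison of isoform intron chains within
each gene, yielding the seven standard local event types: SE (cassette/
skipped exon), A5/A3 (alternative 5'/3' splice site), MX (mutually exclusive
exons), RI (retained intron), AF/AL (alternative first/last exon). PSI is the
fraction of an event's transcript abundance (TPM) carried by the inclusion
isoforms; dPSI is the difference of mean PSI between conditions.

Differential calling uses an exact replicate-label permutation test. With
three replicates per condition a single event admits only 10 distinct label
splits, so by default the permuted |dPSI| null values are pooled across all
testable events to obtain usable p-value resolution; ``pool_null=False``
falls back to the per-event null at its coarse granularity. Benjamini-
Hochberg adjustment is applied across events, and significance additionally
requires |dPSI| above ``dpsi_min`` (strict) and the per-condition expression
gate (total isoform TPM >= ``min_total_tpm``, else PSI is NA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome_model import Annotation, Gene, Transcript

EVENT_TYPES = ("SE", "A5", "A3", "MX", "RI", "AF", "AL")


@dataclass
class ASEvent:
    """A local alternative-splicing event.

    ``coordinates`` are the event-defining genomic anchor positions (type
    specific) used for deduplication; ``inclusion``/``exclusion`` are disjoint
    nonempty transcript-id sets of the same gene.
    """

    id: str
    gene_id: str
    type: str
    inclusion: frozenset[str]
    exclusion: frozenset[str]
    chrom: str
    strand: str
    coordinates: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type}")
        if not self.inclusion or not self.exclusion:
            raise ValueError("inclusion and exclusion sets must be nonempty")
        if self.inclusion & self.exclusion:
            raise ValueError("inclusion and exclusion sets must be disjoint")


@dataclass
class PSIRecord:
    event_id: str
    condition: str
    psi: np.ndarray  # per replicate, NaN when the expression gate fails

    @property
    def mean_psi(self) -> float:
        ok = ~np.isnan(self.psi)
        return float(np.mean(self.psi[ok])) if ok.any() else float("nan")


@dataclass
class DiffSpliceResult:
    event: ASEvent
    psi_control: float
    psi_treated: float
    dpsi: float
    pval: float
    qval: float
    significant: bool
    testable: bool
    dge_status: str = "unchanged"


# ---------------------------------------------------------------------------
# Event generation


def _intron_set(t: Transcript) -> set[tuple[int, int]]:
    return {(i.start, i.end) for i in t.introns}


def _first_last_exons(t: Transcript):
    """(first, last) exon in transcript orientation as (start, end) tuples."""
    e = t.exons_5to3()
    return (e[0].start, e[0].end), (e[-1].start, e[-1].end)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _pair_events(a: Transcript, b: Transcript) -> Iterable[tuple]:
    """Yield raw event tuples (type, coords, inclusion_tx, exclusion_tx)."""
    strand = a.strand
    ia, ib = _intron_set(a), _intron_set(b)
    only_a, only_b = ia - ib, ib - ia
    fa, la = _first_last_exons(a)
    fb, lb = _first_last_exons(b)

    # --- SE: internal exon of one isoform bridged by a single intron in the other
    for x, y in ((a, b), (b, a)):
        other_introns = _intron_set(y)
        exons = x.exons
        for j in range(1, len(exons) - 1):
            e = exons[j]
            up = (exons[j - 1].end, e.start)
            dn = (e.end, exons[j + 1].start)
            if up in _intron_set(x) and dn in _intron_set(x) and (up[0], dn[1]) in other_introns:
                yield ("SE", (up[0], e.start, e.end, dn[1]), x.id, y.id)

    # --- RI: intron of one isoform fully exonic in the other, matching flanks
    for x, y in ((a, b), (b, a)):
        y_exons = {(e.start, e.end) for e in y.exons}
        exons = x.exons
        for j in range(len(exons) - 1):
            u, d = exons[j], exons[j + 1]
            if d.start > u.end and (u.start, d.end) in y_exons:
                # inclusion = the intron-retaining isoform
                yield ("RI", (u.start, u.end, d.start, d.end), y.id, x.id)

    # --- A5/A3: introns sharing one boundary, adjacent exons overlapping
    for sa, ea in only_a:
        for sb, eb in only_b:
            if ea == eb and sa != sb:
                # shared genomic end; differing left boundary
                ua = next(e for e in a.exons if e.end == sa)
                ub = next(e for e in b.exons if e.end == sb)
                if not _overlap((ua.start, ua.end), (ub.start, ub.end)):
                    continue
                etype = "A5" if strand == "+" else "A3"
                # inclusion = variant with the shorter intron (longer exon)
                incl, excl = (a.id, b.id) if sa > sb else (b.id, a.id)
                yield (etype, (min(sa, sb), max(sa, sb), ea), incl, excl)
            elif sa == sb and ea != eb:
                da = next(e for e in a.exons if e.start == ea)
                db = next(e for e in b.exons if e.start == eb)
                if not _overlap((da.start, da.end), (db.start, db.end)):
                    continue
                etype = "A3" if strand == "+" else "A5"
                incl, excl = (a.id, b.id) if ea < eb else (b.id, a.id)
                yield (etype, (sa, min(ea, eb), max(ea, eb)), incl, excl)

    # --- MX: mutually exclusive internal exons sharing both flanking sites
    for j in range(1, len(a.exons) - 1):
        e1 = a.exons[j]
        up1 = (a.exons[j - 1].end, e1.start)
        dn1 = (e1.end, a.exons[j + 1].start)
        if up1 not in ia or dn1 not in ia:
            continue
        for k in range(1, len(b.exons) - 1):
            e2 = b.exons[k]
            up2 = (b.exons[k - 1].end, e2.start)
            dn2 = (e2.end, b.exons[k + 1].start)
            if up2 not in ib or dn2 not in ib:
                continue
            if up1[0] == up2[0] and dn1[1] == dn2[1] and not _overlap(
                (e1.start, e1.end), (e2.start, e2.end)
            ) and (e1.start, e1.end) != (e2.start, e2.end):
                first, second = sorted([(e1.start, e1.end, a.id), (e2.start, e2.end, b.id)])
                # inclusion = variant whose exon is 5'-most in transcript orientation
                incl = first[2] if strand == "+" else second[2]
                excl = second[2] if strand == "+" else first[2]
                yield (
                    "MX",
                    (up1[0], first[0], first[1], second[0], second[1], dn1[1]),
                    incl,
                    excl,
                )

    # --- AF/AL: distinct non-overlapping terminal exons, shared anchor
    if a.introns and b.introns:
        ia5, ib5 = a.introns_5to3(), b.introns_5to3()
        # alternative FIRST exon: first introns share their distal anchor
        anchor_a = ia5[0].end if strand == "+" else ia5[0].start
        anchor_b = ib5[0].end if strand == "+" else ib5[0].start
        if fa != fb and anchor_a == anchor_b and not _overlap(fa, fb):
            first, second = sorted([(fa, a.id), (fb, b.id)])
            # inclusion = the more 5'-distal first exon
            incl = first[1] if strand == "+" else second[1]
            excl = second[1] if strand == "+" else first[1]
            yield ("AF", (first[0][0], first[0][1], second[0][0], second[0][1], anchor_a), incl, excl)
        # alternative LAST exon: last introns share their proximal anchor
        anchor_a = ia5[-1].start if strand == "+" else ia5[-1].end
        anchor_b = ib5[-1].start if strand == "+" else ib5[-1].end
        if la != lb and anchor_a == anchor_b and not _overlap(la, lb):
            first, second = sorted([(la, a.id), (lb, b.id)])
            incl = second[1] if strand == "+" else first[1]
            excl = first[1] if strand == "+" else second[1]
            yield ("AL", (anchor_a, first[0][0], first[0][1], second[0][0], second[0][1]), incl, excl)


def generate_events(annotation: Annotation) -> list[ASEvent]:
    """Enumerate local AS events from all isoform pairs of every gene.

    Duplicate events (same gene, type and coordinates) are merged with
    unioned transcript sets; pairs whose merged inclusion/exclusion sets
    would intersect (pathological annotation redundancy) are dropped.
    """
    merged: dict[tuple, tuple[set[str], set[str]]] = {}
    order: list[tuple] = []
    for gene in annotation.genes.values():
        if len(gene.transcripts) < 2:
            continue
        for a, b in combinations(gene.transcripts, 2):
            for etype, coords, incl, excl in _pair_events(a, b):
                key = (gene.id, etype, gene.chrom, gene.strand, coords)
                if key not in merged:
                    merged[key] = (set(), set())
                    order.append(key)
                merged[key][0].add(incl)
                merged[key][1].add(excl)
    events = []
    for n, key in enumerate(order):
        gene_id, etype, chrom, strand, coords = key
        incl, excl = merged[key]
        if incl & excl:
            continue
        events.append(
            ASEvent(
                id=f"{gene_id};{etype}:{chrom}:{'-'.join(map(str, coords))}:{strand}",
                gene_id=gene_id,
                type=etype,
                inclusion=frozenset(incl),
                exclusion=frozenset(excl),
                chrom=chrom,
                strand=strand,
                coordinates=coords,
            )
        )
    return events


# ---------------------------------------------------------------------------
# PSI


def psi_from_isoform_abundances(included: float, excluded: float) -> float:
    """PSI = included / (included + excluded) for nonnegative abundances."""
    if included < 0 or excluded < 0:
        raise ValueError("abundances must be >= 0")
    total = included + excluded
    if total == 0:
        raise ValueError("PSI undefined: both abundances are zero")
    return included / total


def compute_psi(
    event: ASEvent,
    tpm: pd.DataFrame,
    columns: Sequence[str] | None = None,
    condition: str = "",
    min_total_tpm: float = 0.5,
) -> PSIRecord:
    """Per-replicate PSI of an event from a transcript x replicate TPM table.

    PSI = sum TPM(inclusion) / (sum TPM(inclusion) + sum TPM(exclusion));
    a replicate yields NA when that denominator is below ``min_total_tpm``
    (the isoform-expression gate).
    """
    cols = list(tpm.columns) if columns is None else list(columns)
    for tid in event.inclusion | event.exclusion:
        if tid not in tpm.index:
            raise KeyError(f"transcript {tid} not present in TPM table")
    inc = tpm.loc[sorted(event.inclusion), cols].to_numpy(dtype=float).sum(axis=0)
    exc = tpm.loc[sorted(event.exclusion), cols].to_numpy(dtype=float).sum(axis=0)
    denom = inc + exc
    psi = np.where(denom >= min_total_tpm, inc / np.where(denom > 0, denom, 1.0), np.nan)
    return PSIRecord(event.id, condition, psi)


def _mean_dpsi(psi_t: np.ndarray, psi_c: np.ndarray) -> float:
    ok_t, ok_c = ~np.isnan(psi_t), ~np.isnan(psi_c)
    if not ok_t.any() or not ok_c.any():
        return float("nan")
    return float(psi_t[ok_t].mean() - psi_c[ok_c].mean())


def differential_splicing(
    events: Sequence[ASEvent],
    tpm: pd.DataFrame,
    control_cols: Sequence[str],
    treated_cols: Sequence[str],
    dpsi_min: float = 0.05,
    alpha: float = 0.05,
    min_total_tpm: float = 0.5,
    pool_null: bool = True,
) -> list[DiffSpliceResult]:
    """Call differential splicing between two conditions.

    For each event, per-replicate PSI is computed in both conditions and
    dPSI = mean(treated) - mean(control) over non-NA replicates. The null
    distribution of |dPSI| comes from all distinct reassignments of the
    replicate labels; see the module docstring for the pooled vs per-event
    null. An event is significant iff |dPSI| > ``dpsi_min``, BH-adjusted
    p <= ``alpha``, and both conditions pass the expression gate.
    """
    if len(control_cols) < 2 or len(treated_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    all_cols = list(control_cols) + list(treated_cols)
    n_treat = len(treated_cols)
    # Distinct label splits: choose which columns play "treated". The identity
    # split is dropped, and for balanced designs each unordered partition is
    # kept once (a split and its complement give the same |dPSI|), so the
    # identity's complement does not re-enter the null.
    identity = frozenset(range(len(control_cols), len(all_cols)))
    universe = frozenset(range(len(all_cols)))
    splits: list[set[int]] = []
    seen: set[frozenset] = set()
    for c in combinations(range(len(all_cols)), n_treat):
        fs = frozenset(c)
        if fs == identity:
            continue
        if len(control_cols) == n_treat:
            comp = universe - fs
            if comp == identity:
                continue
            key = frozenset((fs, comp))
            if key in seen:
                continue
            seen.add(key)
        splits.append(set(fs))

    obs: list[float] = []
    psis: list[tuple[np.ndarray, np.ndarray]] = []
    testable: list[bool] = []
    null_per_event: list[np.ndarray] = []
    for ev in events:
        rec_c = compute_psi(ev, tpm, control_cols, "control", min_total_tpm)
        rec_t = compute_psi(ev, tpm, treated_cols, "treated", min_total_tpm)
        psi_all = np.concatenate([rec_c.psi, rec_t.psi])
        d = _mean_dpsi(rec_t.psi, rec_c.psi)
        ok = np.isfinite(d)
        testable.append(ok)
        obs.append(d)
        psis.append((rec_c.psi, rec_t.psi))
        if ok:
            nulls = []
            for s in splits:
                t_mask = np.zeros(len(all_cols), dtype=bool)
                t_mask[list(s)] = True
                nd = _mean_dpsi(psi_all[t_mask], psi_all[~t_mask])
                if np.isfinite(nd):
                    nulls.append(abs(nd))
            null_per_event.append(np.array(nulls))
        else:
            null_per_event.append(np.array([]))

    pvals = np.ones(len(events))
    if pool_null:
        nonempty = [n for n in null_per_event if n.size]
        pooled = np.concatenate(nonempty) if nonempty else np.array([])
        pooled.sort()
        for i, d in enumerate(obs):
            if testable[i] and pooled.size:
                k = pooled.size - np.searchsorted(pooled, abs(d), side="left")
                pvals[i] = (1.0 + k) / (1.0 + pooled.size)
            elif not testable[i]:
                pvals[i] = np.nan
    else:
        for i, d in enumerate(obs):
            if not testable[i]:
                pvals[i] = np.nan
            elif null_per_event[i].size:
                k = int((null_per_event[i] >= abs(d)).sum())
                pvals[i] = (1.0 + k) / (1.0 + null_per_event[i].size)

    ok_mask = np.isfinite(pvals)
    qvals = np.full(len(events), np.nan)
    if ok_mask.any():
        qvals[ok_mask] = multipletests(pvals[ok_mask], method="fdr_bh")[1]

    results = []
    for i, ev in enumerate(events):
        psi_c, psi_t = psis[i]
        mc = float(np.nanmean(psi_c)) if np.isfinite(psi_c).any() else float("nan")
        mt = float(np.nanmean(psi_t)) if np.isfinite(psi_t).any() else float("nan")
        sig = bool(
            testable[i]
            and abs(obs[i]) > dpsi_min
            and np.isfinite(qvals[i])
            and qvals[i] <= alpha
        )
        results.append(
            DiffSpliceResult(
                event=ev,
                psi_control=mc,
                psi_treated=mt,
                dpsi=obs[i],
                pval=float(pvals[i]),
                qval=float(qvals[i]),
                significant=sig,
                testable=bool(testable[i]),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Summaries


def summarize_event_types(results: Sequence[DiffSpliceResult]) -> dict[str, int]:
    """Counts of significant events by type (types with zero count omitted)."""
    out: dict[str, int] = {}
    for r in results:
        if r.significant:
            out[r.event.type] = out.get(r.event.type, 0) + 1
    return out


def crosstab_as_dge(
    results: Sequence[DiffSpliceResult],
    genes_up: set[str],
    genes_down: set[str],
) -> dict[str, int]:
    """Significant AS events by the expression status of their host gene.

    Genes absent from both call sets count as "unchanged". Also sets
    ``dge_status`` on each significant result.
    """
    counts = {"UP": 0, "DOWN": 0, "unchanged": 0}
    for r in results:
        if not r.significant:
            continue
        if r.event.gene_id in genes_up:
            r.dge_status = "UP"
        elif r.event.gene_id in genes_down:
            r.dge_status = "DOWN"
        else:
            r.dge_status = "unchanged"
        counts[r.dge_status] += 1
    return counts
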