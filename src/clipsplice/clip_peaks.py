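"""Peak calling, replicate union and specificity filtering for CLIP reads.

The filtering stage implements the peak-to-region specificity statistic:
reads overlapping a peak divided by reads overlapping the peak extended by
one peak-width on each side. Candidate peaks with at least ``min_merged_reads``
reads in the merged IP data are kept, and of those, peaks whose ratio is
greater than or equal to the arithmetic mean ratio of the candidate set are
selected. Diffuse, nonspecifically mapping regions produce low ratios and are
removed by this rule.

The internal candidate caller is an explicit one-sided Poisson test of IP
coverage against a locally estimated control rate (two window sizes plus a
global floor). It is a documented stand-in for an external broad-peak caller;
``mode="import"`` passes externally called scored peaks through instead.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import poisson

from .genome_model import GenomicInterval

LOG10 = np.log(10.0)


@dataclass
class ReadSet:
    """A labelled set of stranded aligned-read intervals with a lazy index."""

    label: str
    reads: list[GenomicInterval]

    _index: dict | None = field(default=None, repr=False, compare=False)

    def total(self) -> int:
        return len(self.reads)

    def _build_index(self) -> dict:
        if self._index is None:
            idx: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
            groups: dict[tuple[str, str], list[GenomicInterval]] = {}
            for r in self.reads:
                groups.setdefault((r.chrom, r.strand), []).append(r)
            for key, rs in groups.items():
                starts = sorted(r.start for r in rs)
                ends = sorted(r.end for r in rs)
                idx[key] = (starts, ends)
            self._index = idx
        return self._index

    def count_overlapping(self, chrom: str, start: int, end: int, strand: str) -> int:
        """Number of same-strand reads overlapping [start, end) by >= 1 nt."""
        idx = self._build_index().get((chrom, strand))
        if idx is None:
            return 0
        starts, ends = idx
        # reads with start < end minus reads with end <= start
        return bisect_left(starts, end) - bisect_right(ends, start)

    def chrom_strand_keys(self) -> list[tuple[str, str]]:
        return sorted(self._build_index().keys())

    def span_end(self, chrom: str, strand: str) -> int:
        idx = self._build_index().get((chrom, strand))
        return idx[1][-1] if idx else 0


def merge_readsets(readsets: Sequence[ReadSet], label: str = "merged") -> ReadSet:
    reads: list[GenomicInterval] = []
    for rs in readsets:
        reads.extend(rs.reads)
    return ReadSet(label, reads)


@dataclass(frozen=True)
class CandidatePeak:
    """A candidate peak: an interval plus a -log10 p-value enrichment score."""

    interval: GenomicInterval
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("peak score must be >= 0")


@dataclass
class FilteredPeak:
    """A candidate peak with specificity counts and selection flags."""

    interval: GenomicInterval
    score: float
    peak_count: int
    region_count: int
    ratio: float
    per_replicate_counts: list[int] = field(default_factory=list)
    n_supporting_replicates: int = 0
    selected: bool = False


# ---------------------------------------------------------------------------
# Pile-up


def pileup(readset: ReadSet, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
    """Per-position coverage over [start, end) on one strand.

    Coverage at position p is the number of same-strand reads with
    start <= p < end.
    """
    if end <= start:
        raise ValueError("pileup span must be nonempty")
    cov = np.zeros(end - start, dtype=np.int64)
    diff = np.zeros(end - start + 1, dtype=np.int64)
    for r in readset.reads:
        if r.chrom != chrom or r.strand != strand:
            continue
        s = max(r.start, start)
        e = min(r.end, end)
        if s < e:
            diff[s - start] += 1
            diff[e - start] -= 1
    np.cumsum(diff[:-1], out=cov)
    return cov


def _coverage_array(reads: list[GenomicInterval], length: int) -> np.ndarray:
    diff = np.zeros(length + 1, dtype=np.float64)
    for r in reads:
        if r.start < length:
            diff[r.start] += 1
            diff[min(r.end, length)] -= 1
    return np.cumsum(diff[:-1])


def _sliding_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation."""
    n = len(x)
    if window >= n:
        return np.full(n, x.mean())
    cs = np.concatenate([[0.0], np.cumsum(x)])
    half = window // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + window - half, 0, n)
    return (cs[hi] - cs[lo]) / np.maximum(hi - lo, 1)


def _merge_positions(pos: np.ndarray, scores: np.ndarray, gap_max: int):
    """Group sorted significant positions allowing gaps <= gap_max."""
    if len(pos) == 0:
        return []
    breaks = np.where(np.diff(pos) > gap_max + 1)[0]
    out = []
    begin = 0
    for b in list(breaks) + [len(pos) - 1]:
        seg = slice(begin, b + 1)
        out.append((int(pos[seg][0]), int(pos[seg][-1]) + 1, float(scores[seg].max())))
        begin = b + 1
    return out


def call_candidate_peaks(
    ip_replicates: Sequence[ReadSet],
    control: ReadSet,
    min_score: float = 10.0,
    mode: str = "internal",
    gap_max: int = 50,
    lambda_min: float = 0.05,
    small_window: int = 1000,
    large_window: int = 10000,
    import_peaks: Sequence[Sequence[CandidatePeak]] | None = None,
) -> list[list[CandidatePeak]]:
    """Call candidate peaks per IP replicate against a control read set.

    Internal mode: for each position, a one-sided Poisson tail p-value of the
    IP coverage against ``lambda = max(control coverage smoothed over
    small/large windows and scaled to IP depth, genome-wide control rate,
    lambda_min)``. Positions with ``-log10 p >= min_score`` are merged into
    peaks allowing gaps of at most ``gap_max`` nt; a peak's score is the
    maximum positional score.

    Import mode: externally called scored peaks (one list per replicate) are
    thresholded at ``min_score`` and passed through.
    """
    if mode == "import":
        if import_peaks is None:
            raise ValueError("import mode requires import_peaks")
        return [[p for p in rep if p.score >= min_score] for rep in import_peaks]
    if mode != "internal":
        raise ValueError(f"unknown mode {mode!r}")
    if control.total() == 0 and lambda_min <= 0:
        raise ValueError("control has no reads and lambda floor is 0")

    results: list[list[CandidatePeak]] = []
    ctrl_groups: dict[tuple[str, str], list[GenomicInterval]] = {}
    for r in control.reads:
        ctrl_groups.setdefault((r.chrom, r.strand), []).append(r)

    for rep in ip_replicates:
        peaks: list[CandidatePeak] = []
        if rep.total() == 0:
            results.append(peaks)
            continue
        scale = rep.total() / control.total() if control.total() > 0 else 0.0
        ip_groups: dict[tuple[str, str], list[GenomicInterval]] = {}
        for r in rep.reads:
            ip_groups.setdefault((r.chrom, r.strand), []).append(r)
        for key, ip_reads in ip_groups.items():
            length = max(r.end for r in ip_reads)
            creads = ctrl_groups.get(key, [])
            if creads:
                length = max(length, max(r.end for r in creads))
            ip_cov = _coverage_array(ip_reads, length)
            if creads:
                ctrl_cov = _coverage_array(creads, length) * scale
                lam = np.maximum(
                    _sliding_mean(ctrl_cov, small_window),
                    _sliding_mean(ctrl_cov, large_window),
                )
                lam = np.maximum(lam, ctrl_cov.mean())
            else:
                lam = np.zeros(length)
            lam = np.maximum(lam, lambda_min)
            # only positions with some minimum coverage can be significant
            mask = ip_cov >= 3
            if not mask.any():
                continue
            k = ip_cov[mask]
            scores = -poisson.logsf(k - 1, lam[mask]) / LOG10
            sig = scores >= min_score
            if not sig.any():
                continue
            pos = np.nonzero(mask)[0][sig]
            chrom, strand = key
            for s, e, sc in _merge_positions(pos, scores[sig], gap_max):
                peaks.append(CandidatePeak(GenomicInterval(chrom, s, e, strand), sc))
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.strand, p.interval.start))
        results.append(peaks)
    return results


def union_peaks(per_replicate_peaks: Sequence[Sequence[CandidatePeak]]) -> list[CandidatePeak]:
    """Merge overlapping same-strand peaks across replicates (score = max)."""
    allp = sorted(
        (p for rep in per_replicate_peaks for p in rep),
        key=lambda p: (p.interval.chrom, p.interval.strand, p.interval.start, p.interval.end),
    )
    out: list[CandidatePeak] = []
    for p in allp:
        if out:
            q = out[-1]
            if (
                q.interval.chrom == p.interval.chrom
                and q.interval.strand == p.interval.strand
                and p.interval.start < q.interval.end
            ):
                merged = GenomicInterval(
                    q.interval.chrom,
                    q.interval.start,
                    max(q.interval.end, p.interval.end),
                    q.interval.strand,
                )
                out[-1] = CandidatePeak(merged, max(q.score, p.score))
                continue
        out.append(p)
    return out


def count_peak_and_region(peak: GenomicInterval, merged_ip: ReadSet) -> tuple[int, int]:
    """Reads overlapping the peak and the peak extended by one width per side.

    A read counts if it overlaps by >= 1 nt on the same strand. The region is
    clipped at coordinate 0, so ``peak_count <= region_count`` always.
    """
    w = peak.width
    peak_count = merged_ip.count_overlapping(peak.chrom, peak.start, peak.end, peak.strand)
    region_count = merged_ip.count_overlapping(
        peak.chrom, max(0, peak.start - w), peak.end + w, peak.strand
    )
    return peak_count, region_count


def filter_peaks(
    candidates: Sequence[CandidatePeak],
    merged_ip: ReadSet,
    min_merged_reads: int = 5,
    gate_first: bool = True,
) -> tuple[list[FilteredPeak], dict]:
    """Apply the read-count gate and the mean-ratio specificity filter.

    Candidates with ``peak_count >= min_merged_reads`` form the candidate set;
    the selection threshold is the arithmetic mean of their peak/region ratios
    and candidates with ``ratio >= threshold`` are selected. With
    ``gate_first=False`` the mean is instead computed over all peaks with a
    nonzero region count, before the read-count gate.

    Returns the full list of :class:`FilteredPeak` (``selected`` flags set)
    plus a summary dict reporting the threshold and counts.
    """
    peaks: list[FilteredPeak] = []
    for c in candidates:
        pc, rc = count_peak_and_region(c.interval, merged_ip)
        ratio = pc / rc if rc > 0 else float("nan")
        peaks.append(FilteredPeak(c.interval, c.score, pc, rc, ratio))

    gated = [p for p in peaks if p.peak_count >= min_merged_reads]
    if gate_first:
        pool = [p.ratio for p in gated if p.region_count > 0]
    else:
        pool = [p.ratio for p in peaks if p.region_count > 0]
    threshold = float(np.mean(pool)) if pool else float("nan")
    n_selected = 0
    for p in gated:
        if p.region_count > 0 and p.ratio >= threshold:
            p.selected = True
            n_selected += 1
    summary = {
        "n_input_peaks": len(peaks),
        "n_candidates": len(gated),
        "ratio_threshold": threshold if pool else None,
        "n_selected": n_selected,
    }
    return peaks, summary


def replicate_support(
    selected_peaks: Sequence[FilteredPeak],
    per_replicate_reads: Sequence[ReadSet],
    min_reads: int = 5,
) -> dict:
    """Count per-replicate read support for selected peaks.

    Fills ``per_replicate_counts`` and ``n_supporting_replicates`` on each
    peak (a replicate supports a peak if >= ``min_reads`` of its reads overlap
    it) and returns counts/integer percentages of peaks supported in >= 1 and
    >= 2 replicates.
    """
    n_ge1 = n_ge2 = 0
    for p in selected_peaks:
        counts = [
            rs.count_overlapping(p.interval.chrom, p.interval.start, p.interval.end, p.interval.strand)
            for rs in per_replicate_reads
        ]
        p.per_replicate_counts = counts
        p.n_supporting_replicates = sum(c >= min_reads for c in counts)
        if p.n_supporting_replicates >= 1:
            n_ge1 += 1
        if p.n_supporting_replicates >= 2:
            n_ge2 += 1
    n = len(selected_peaks)
    return {
        "n_selected": n,
        "supported_ge1": n_ge1,
        "supported_ge2": n_ge2,
        "pct_ge1": support_percentage(n_ge1, n),
        "pct_ge2": support_percentage(n_ge2, n),
    }


def support_percentage(k: int, n: int) -> int | None:
    """Integer-rounded percentage k/n, or None for an empty selection."""
    if n == 0:
        return None
    return int(round(100.0 * k / n))


def peak_width_quartiles(peaks: Sequence[FilteredPeak | CandidatePeak]) -> tuple[float, float]:
    """First and third quartile of peak widths (linear interpolation)."""
    if not peaks:
        raise ValueError("no peaks")
    widths = np.array([p.interval.width for p in peaks], dtype=float)
    q1, q3 = np.percentile(widths, [25, 75])
    return float(q1), float(q3)


def replicate_correlation(counts: np.ndarray, cap: int | None = None) -> np.ndarray:
    """Pairwise Pearson correlation of raw per-peak counts across replicates.

    ``counts`` is peaks x replicates; ``cap`` optionally truncates counts to
    suppress outliers before correlating.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a peaks x replicates matrix with >= 2 replicates")
    if cap is not None:
        counts = np.minimum(counts, cap)
    return np.corrcoef(counts, rowvar=False)
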