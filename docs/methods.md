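# Methods

This note documents the models and procedures implemented in `clipsplice`,
the defaults that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show
about real data.

## Coordinates and data model

All internal coordinates are 0-based half-open; GTF's 1-based closed
convention is converted only at file boundaries (`read_annotation` /
`write_gtf`), so no other code ever reasons about inclusive ends. Strand is
mandatory on reads and peaks: single-end enhanced CLIP is strand-specific
(the library protocol restores read orientation by reverse-complementation),
so an unstranded record in a CLIP input is an error; BED reading offers a
configurable default strand for non-CLIP uses. Transcripts missing a CDS are
treated as non-coding for feature labelling. Biotypes beyond protein-coding,
lincRNA and antisense are aggregated into short-noncoding, pseudogene and
other buckets through a configurable map, since annotation releases differ
in their fine-grained vocabularies.

## Candidate peak calling

The internal caller is a deliberately simple, fully specified stand-in for
an external broad-peak caller: per position it computes a one-sided Poisson
tail probability of the IP coverage against a local control rate

    lambda = max(control coverage averaged over 1 kb, over 10 kb,
                 genome-wide control rate, lambda_min = 0.05),

with control coverage scaled by (IP reads / control reads). Positions with
−log10 p ≥ 10 are merged into peaks allowing ≤ 50 nt gaps; the peak score is
the maximal positional score. When an external caller's scored peaks are
available, import mode passes them through after the same score threshold
and is the higher-fidelity path. The caller's absolute sensitivity is not
the point — the filtering stage downstream is.

## Specificity filtering

Candidate peaks from all replicates are unioned (same-strand overlapping
intervals merged, max score kept). For each peak the merged-IP reads
overlapping the peak and the peak ± one peak-width are counted (≥ 1 nt
same-strand overlap; the simplest rule consistent with a count-based ratio,
since union-style counters do not specify one). Peaks with ≥ 5 merged reads
form the candidate set; the selection threshold is the arithmetic mean of
their peak/region ratios, and candidates at or above the mean are selected.
The threshold is computed after the read-count gate (the reported mean
plausibly refers to the analysed candidate set; `gate_first=False` computes
it before the gate instead) and is reported in the run summary. Replicate
support counts, integer-rounded support percentages, width quartiles
(linear interpolation) and pairwise Pearson correlations of raw per-peak
counts (optionally truncated at a cap) complete the module.

The mean-ratio rule presupposes a mixed population: it separates sharp
specific peaks (ratio near 1) from diffuse nonspecific regions (low ratio).
On a dataset containing only sharp peaks the rule would, by construction,
discard roughly the lower half of a homogeneous ratio distribution; see the
synthetic-data section for how the benchmark reflects this.

## Peak annotation

Feature spans per transcript (5'UTR, coding exon, 3'UTR, intron, with plain
exons for non-coding transcripts) partition the transcript span. A peak's
category is the label with the largest base overlap among same-strand
overlapping transcripts; ties are broken by the precedence coding-exon >
5'UTR > 3'UTR > intron (configurable), and remaining ties by transcript id
so that results are invariant under mirroring the genome. Exon-ordinal
classes (first/mid/last exon or intron, strand-aware) are computed against a
representative transcript per gene — the one with most exons, ties by span —
because per-gene aggregation needs a single exon numbering; genes whose
representative has fewer than three exons yield NA. A peak is
junction-spanning when it covers ≥ 1 nt on each side of an annotated
exon–intron boundary.

Metagene profiles average strand-oriented coverage in a ±50 nt window around
exon–intron boundaries (default: exon 3' end / intron start, position 0 =
first intronic base; the acceptor side is also available, as are peaks
instead of reads as input — both choices are exposed because either input is
defensible). Duplicate boundaries shared by isoforms are counted once.

Biotype distributions sum per-gene read counts normalized per million mapped
reads within each sample; a read counts for every same-strand gene body it
overlaps. Four regimes are reported: all genes, genes whose normalized IP
is ≥ 1.5× the negative control, genes enriched over the input, and both.
The input-gate fold also defaults to 1.5 — the enrichment-over-input fold is
not quantified anywhere we could anchor it — and the per-million
normalization is recorded in output metadata as an assumption.

## Alternative splicing

Events are enumerated by pairwise comparison of isoform intron chains within
a gene: SE (internal exon bridged by a single intron in the other chain),
RI (intron fully exonic in the other chain with matching flanks), A5/A3
(introns sharing one splice site, adjacent exons overlapping; labels are
strand-aware), MX (mutually exclusive internal exons sharing both flanking
sites), AF/AL (non-overlapping terminal exons spliced to a shared anchor).
Duplicate events by exact coordinates are merged with unioned transcript
sets; near-duplicates from annotation redundancy stay distinct. Inclusion
conventions: SE the exon-containing isoforms, RI the retaining isoforms,
A5/A3 the shorter-intron variant, MX/AF the 5'-most alternative exon, AL the
3'-most. Downstream analyses align event polarity against ground truth by
the transcript sets, so the convention only needs to be deterministic.

PSI per replicate is the inclusion share of the event's total TPM, NA below
0.5 TPM. dPSI is the difference of mean PSI over non-NA replicates, treated
(knockdown) minus control, so a gain of exon inclusion upon knockdown is
positive. Significance requires |dPSI| strictly greater than 0.05 (the
strict reading of the threshold; the boundary value 0.05 itself is not
called), BH-adjusted p ≤ 0.05, and both conditions passing the expression
gate.

**Permutation null.** p-values come from exact replicate-label permutation:
every distinct reassignment of the condition labels, excluding the identity
partition (for balanced designs each unordered partition is used once, since
a split and its complement give the same |dPSI|). With 3 + 3 replicates a
single event admits only 10 distinct partitions, so a per-event p-value
cannot fall below 0.1 and no event could ever pass α = 0.05. The package
therefore pools the permuted |dPSI| values across all testable events into a
common null by default — the same resolution-restoring move made by
empirical-null splicing tools, without conditioning on expression — giving
p = (1 + #{pooled null ≥ |dPSI|}) / (1 + N_pooled). The per-event formula
remains available (`pool_null=False`) for inspection at its coarse
granularity. Pooling assumes events' null |dPSI| values are roughly
exchangeable; strongly heteroscedastic event sets weaken the per-event
calibration (conservatively, when a few high-variance events fatten the
pooled null).

## Expression consistency and coregulation

Stat tables carry a signed effect b on the natural-log scale (positive = up
in knockdown) and a BH-adjusted q. The consistency rule is applied at
q ≤ 0.005 at both levels; genes significant only at the gene level are
called by the gene-level sign (the rule's parenthetical covers only genes
that do have significant transcripts; `gene_only_ok=False` restricts to
transcript-supported calls). Significant genes with b = 0 have no direction
and are excluded with a warning. Note one non-obvious consequence of the
rule: tightening q can remove a discordant transcript from significance and
thereby re-admit a previously mixed-excluded gene, so the called sets are
not strictly monotone in q — only the pool of significant genes is.

Coregulation between two knockdowns reports Venn counts of the up/down call
sets, the integer-rounded percentage of A's up set shared with B, and the
Pearson correlation of gene-level effects over the common differentially
expressed genes (significant in both experiments at q ≤ 0.005, either
direction), with per-gene direction classes.

## Synthetic data generator

The generator emulates the statistical structure of a strand-specific CLIP
experiment with five IP replicates plus knockdown RNA-seq with three
replicates per condition. Defaults (all overridable): 200 genes of 3–8 exons
(80–300 nt exons, 200–1500 nt introns) on one chromosome; 75% protein-coding
with the remainder split across lincRNA/antisense/short-noncoding/pseudogene/
other; 200 planted peaks at rate 30 reads/peak/replicate, half anchored at
exon 3' ends so reads straddle the boundary; Poisson background of
0.01 reads/nt of gene body in every sample; reads 30–60 nt (motivated by
50 nt single-end libraries) with Gaussian anchor jitter (sd 5 nt). One RNG
stream per generator, derived from the master seed by fixed spawn keys, so
enabling one component never perturbs another; fixed seeds give
bit-identical outputs.

**Nonspecific sticky regions.** In addition to planted peaks, each IP
replicate receives 60 diffuse pile-ups: a tight core (15 reads/replicate,
sd 6 nt) that the caller detects, surrounded by a ±150 nt plateau of
0.08 reads/nt/replicate — kept below the caller's positional detection
limit so only the core is called while the plateau populates the region
flanks. These emulate the nonspecifically mapping sticky loci that the
specificity ratio exists to remove; without them every candidate would be a
true peak, the ratio distribution would be homogeneous, and the mean-ratio
rule would necessarily discard about half of the truth (see the filtering
section). With them, the benchmark reproduces the intended regime: specific
peaks ratio ≈ 0.94, sticky regions ≈ 0.6, mean threshold ≈ 0.90, and the
selected set recovers planted peaks with precision ≈ 0.99 and recall ≈ 0.96.

**Expression.** Baseline transcript TPMs are log-normal (meanlog 1.5,
sdlog 1.0); 15% of genes are planted up and 15% down per knockdown at
±1.5 natural-log units, with 25% of knockdown A's up (and down) genes shared
with knockdown B. Planted AS events (default: eight cassette-exon and eight
alternative-first-exon events at ΔPSI = 0.4, the two types that dominate
such knockdowns) are realized by shifting isoform shares of a 20-TPM gene in
knockdown A; replicate noise is log-normal (sd 0.15) and each replicate
column is renormalized to 10^6, which preserves within-gene isoform shares.
Stat tables come from a plain two-sample t-test on log TPM with BH
adjustment — deliberately not an emulation of any quantifier's inferential
model, since downstream rules consume only (id, b, q).

**What the benchmark does not show.** The generator has no alignment error,
no multimapping or repeat-derived reads, no UMI duplication, no GC or
positional bias, no overdispersion beyond log-normal noise, and its sticky
regions are a stylized stand-in for nonspecific binding. Passing recovery
tests therefore demonstrates the correctness of the implemented rules under
their own assumptions, not end-to-end performance on real libraries. Library
depth is in the 10^4–10^5 read range per replicate, consistent with the
scale of deduplicated single-end CLIP libraries, but no distributional claim
about any real dataset is implied.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use the generator defaults above
(200 genes, 200 + 60 planted regions, 5 replicates; 40 planted ΔPSI = 0.4
events for splicing recovery; 2000 single-event nulls for the type-I check;
20 simulation seeds for the coregulation summary). These sizes give
Monte-Carlo stable summaries in seconds. Quartiles use linear interpolation;
percentages in summaries are integer-rounded, matching the reporting style
of the counts they mirror; empty candidate sets report an undefined
threshold and empty selections rather than erroring; p-values from empty or
fully gated events are NA and excluded from BH adjustment.
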