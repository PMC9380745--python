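# clipsplice

Analysis pipeline for studying an RNA-binding protein that acts both in
nonsense-mediated mRNA decay (NMD) and in pre-mRNA splicing. It covers the
computational stages such a study needs downstream of read alignment and
transcript quantification:

* **CLIP peak specificity filtering** — from aligned-read intervals of
  several IP replicates, a negative-control IP and a size-matched input:
  candidate peak calling (or import of externally called scored peaks),
  union across replicates, and filtering by the peak-to-region specificity
  ratio with replicate-support accounting.
* **Peak annotation** — feature category (5'UTR / exon / intron / 3'UTR /
  intergenic), first/mid/last exon-ordinal classes, junction-spanning flags,
  metagene profiles around exon–intron boundaries, and enrichment-gated
  biotype read distributions.
* **Alternative splicing** — local AS events (SE, A5, A3, MX, RI, AF, AL)
  from transcript models, PSI from isoform TPMs, and differential dPSI
  calling with a replicate-label permutation test.
* **Knockdown coregulation** — the gene/transcript direction-consistency
  rule for differential-expression tables and overlap/correlation summaries
  between two knockdowns.
* **Synthetic data** — a first-class generator producing annotations, CLIP
  read sets and expression/statistics tables with known ground truth, so
  every stage is testable without sequencing data.

Intended users: computational biologists analysing CLIP + knockdown RNA-seq
experiments, and anyone needing a transparent, tested reference
implementation of these filtering and quantification rules.

## The statistics at the core

**Peak-to-region ratio.** For a candidate peak of width *w*, let
*peak_count* be the reads overlapping the peak (≥ 1 nt, same strand) in the
merged IP data and *region_count* the reads overlapping the peak extended by
*w* on each side. The specificity ratio is

    ratio = peak_count / region_count  ∈ (0, 1].

Peaks with at least 5 merged reads form the candidate set; a peak is
selected when its ratio is ≥ the arithmetic mean ratio of that set. Sharp,
specific binding gives ratios near 1; diffuse nonspecific pile-ups spread
reads into the flanks and fall below the mean.

**PSI / dPSI.** For an event with inclusion isoform set *I* and exclusion
set *E*,

    PSI = Σ_{t∈I} TPM_t / (Σ_{t∈I} TPM_t + Σ_{t∈E} TPM_t),

undefined (NA) when the denominator is below 0.5 TPM. dPSI is the difference
of mean PSI (treated − control); significance requires |dPSI| > 0.05 and a
Benjamini–Hochberg adjusted permutation p ≤ 0.05.

**Consistency rule.** A gene is consistently regulated when its gene-level
q ≤ 0.005 and every transcript with q ≤ 0.005 has an effect *b* (natural-log
scale, positive = up in knockdown) of the same sign as the gene-level *b*;
mixed transcript signs exclude the gene.

## Worked example

```python
from clipsplice import *
from clipsplice.clip_peaks import merge_readsets
from clipsplice.synthetic_data import (
    SimulationConfig, simulate_annotation, simulate_clip_reads, simulate_expression)

cfg = SimulationConfig(seed=7)            # 200 genes, 200 planted peaks, 5 IP reps
ann, truth = simulate_annotation(cfg)
clip = simulate_clip_reads(ann, truth, cfg)

per_rep = call_candidate_peaks(clip.ip_replicates, clip.negative)
peaks, summary = filter_peaks(union_peaks(per_rep), merge_readsets(clip.ip_replicates))
selected = [p for p in peaks if p.selected]
support = replicate_support(selected, clip.ip_replicates)

expr = simulate_expression(ann, truth, cfg)
results = differential_splicing(generate_events(ann), expr.tpm,
                                expr.columns["ctrl"], expr.columns["kdA"])
calls_a = call_consistent_genes(expr.gene_stats["A"], expr.transcript_stats["A"])
calls_b = call_consistent_genes(expr.gene_stats["B"], expr.transcript_stats["B"])
```

This prints (via the obvious `print` statements):

```
candidates: 256   mean peak/region ratio: 0.90
selected: 188   supported >=1 rep: 100%   >=2 reps: 100%
peak widths (Q1-Q3): 51-55 nt
significant AS events by type: {'SE': 8, 'AF': 8}
knockdown A up: 20   shared with B: 7 (35%)   Pearson r = 0.73
```

Reading: of 256 candidate peaks passing the 5-read gate, 188 sit at or above
the mean specificity ratio of 0.90 — these recover the planted peaks with
high precision while the planted nonspecific sticky regions fall below the
mean. All 16 planted dPSI = 0.4 events (8 cassette-exon, 8 alternative-first-
exon) are called significant. Knockdown B shares 7 of A's 20 consistently
up-regulated genes, and the gene-level effects of the common differentially
expressed genes correlate strongly.

The same stages are scriptable from the shell via the `clipsplice` command
(`clipsplice simulate`, `clipsplice clip call|filter|annotate|metagene|biotypes`,
`clipsplice splice events|diff`, `clipsplice dge consistent|coregulate`).

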