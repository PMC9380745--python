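"""Gene/transcript differential-expression consistency calling and
coregulation between two knockdowns.

A gene is called consistently regulated when it is significant at the gene
level (q <= 0.005 by default) and every significant transcript of that gene
changes in the same direction as the gene-level effect b (natural-log scale,
positive = up in knockdown). Genes whose significant transcripts disagree in
sign are excluded as mixed. Coregulation between two knockdowns is summarised
as Venn counts of the up/down call sets, the percentage of one up set shared
with the other, and the Pearson correlation of effect sizes over genes
significant in both experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

GENE_STAT_COLUMNS = ["gene_id", "b", "qval"]
TRANSCRIPT_STAT_COLUMNS = ["transcript_id", "gene_id", "b", "qval"]


@dataclass
class ConsistentCallSet:
    genes_up: set[str] = field(default_factory=set)
    genes_down: set[str] = field(default_factory=set)
    excluded_mixed: set[str] = field(default_factory=set)


def _validate_stats(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing columns {missing}")
    q = df["qval"].to_numpy(dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError(f"{name} table has q-values outside [0, 1]")


def call_consistent_genes(
    gene_stats: pd.DataFrame,
    transcript_stats: pd.DataFrame,
    q_threshold: float = 0.005,
    gene_only_ok: bool = True,
) -> ConsistentCallSet:
    """Apply the gene/transcript direction-consistency rule.

    A gene with gene-level q <= ``q_threshold`` is called up (or down) when
    all of its transcripts with q <= ``q_threshold`` have b of the same sign
    as the gene-level b; mixed transcript signs exclude the gene. Genes
    significant at the gene level with no significant transcript are called
    by the gene-level sign when ``gene_only_ok`` (default), else skipped.
    Significant genes with b == 0 are excluded with a warning.
    """
    _validate_stats(gene_stats, GENE_STAT_COLUMNS, "gene")
    _validate_stats(transcript_stats, TRANSCRIPT_STAT_COLUMNS, "transcript")

    sig_tx = transcript_stats[transcript_stats["qval"] <= q_threshold]
    tx_signs = sig_tx.groupby("gene_id")["b"].agg(lambda s: set(np.sign(s)))

    calls = ConsistentCallSet()
    sig_genes = gene_stats[gene_stats["qval"] <= q_threshold]
    for rec in sig_genes.itertuples(index=False):
        if rec.b == 0:
            logger.warning("gene %s significant with b = 0; direction undefined, excluded", rec.gene_id)
            calls.excluded_mixed.add(rec.gene_id)
            continue
        gene_sign = 1.0 if rec.b > 0 else -1.0
        signs = tx_signs.get(rec.gene_id)
        if signs is None:
            if not gene_only_ok:
                continue
        elif signs != {gene_sign}:
            calls.excluded_mixed.add(rec.gene_id)
            continue
        (calls.genes_up if gene_sign > 0 else calls.genes_down).add(rec.gene_id)
    return calls


def overlap_up_sets(calls_a: ConsistentCallSet, calls_b: ConsistentCallSet) -> dict:
    """Venn counts of the two call sets plus the shared-up percentage of A.

    The percentage is integer-rounded ``100 * |A_up & B_up| / |A_up|``; it is
    None when A's up set is empty.
    """
    shared_up = calls_a.genes_up & calls_b.genes_up
    shared_down = calls_a.genes_down & calls_b.genes_down
    n_a = len(calls_a.genes_up)
    return {
        "n_A_up": n_a,
        "n_B_up": len(calls_b.genes_up),
        "n_shared_up": len(shared_up),
        "n_A_down": len(calls_a.genes_down),
        "n_B_down": len(calls_b.genes_down),
        "n_shared_down": len(shared_down),
        "pct_A_up_shared": int(round(100.0 * len(shared_up) / n_a)) if n_a else None,
    }


def correlate_changes(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    q_threshold: float = 0.005,
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of effects over common differentially expressed genes.

    The gene universe is genes with q <= ``q_threshold`` in both experiments
    (either direction). Returns r and a per-gene table with ``b_A``, ``b_B``
    and a direction class in {up-up, down-down, discordant}.
    """
    _validate_stats(stats_a, GENE_STAT_COLUMNS, "gene A")
    _validate_stats(stats_b, GENE_STAT_COLUMNS, "gene B")
    a = stats_a[stats_a["qval"] <= q_threshold].set_index("gene_id")["b"]
    b = stats_b[stats_b["qval"] <= q_threshold].set_index("gene_id")["b"]
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need >= 3 common differentially expressed genes")
    ba, bb = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    if np.std(ba) == 0 or np.std(bb) == 0:
        raise ValueError("zero variance in effect sizes; correlation undefined")
    r = float(pearsonr(ba, bb)[0])
    cls = np.where(
        (ba > 0) & (bb > 0), "up-up", np.where((ba < 0) & (bb < 0), "down-down", "discordant")
    )
    table = pd.DataFrame({"gene_id": common, "b_A": ba, "b_B": bb, "direction": cls})
    return r, table
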