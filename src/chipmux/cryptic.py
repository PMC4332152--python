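"""Calling genes with increased internal transcription initiation.

5'-end tags are filtered (unique alignment, no 5' soft-clipping, at most
10% of the read soft-clipped in total), counted per gene beyond the first
200 bp of the gene body (strand-matched, transcription-oriented), and
compared between conditions with the negative-binomial Wald test under
median-of-ratios size factors.  A gene is called when its log2 fold change
is positive and its BH-adjusted p-value falls below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diffstats import benjamini_hochberg, nb_wald_test
from .genome import GenomeModel

__all__ = [
    "TagFilterReport",
    "filter_tss_reads",
    "internal_counts",
    "median_of_ratios",
    "call_internal_initiation",
]

DEFAULT_EXCLUSION = 200
TAG_COLUMNS = [
    "chromosome",
    "five_prime_position",
    "strand",
    "n_alignments",
    "softclip_5prime",
    "softclip_total_fraction",
]


@dataclass
class TagFilterReport:
    total: int = 0
    kept: int = 0
    multi_aligned: int = 0
    softclipped_5prime: int = 0
    softclipped_fraction: int = 0


def filter_tss_reads(
    tags: pd.DataFrame, max_softclip_fraction: float = 0.10
) -> tuple[pd.DataFrame, TagFilterReport]:
    """Keep uniquely aligned tags with clean 5' ends.

    Excludes tags with multiple alignments, any 5' soft-clipped bases, or
    soft-clipping over more than ``max_softclip_fraction`` of the read.
    """
    report = TagFilterReport(total=len(tags))
    multi = tags["n_alignments"] != 1
    clip5 = ~multi & (tags["softclip_5prime"] > 0)
    clipfrac = ~multi & ~clip5 & (tags["softclip_total_fraction"] > max_softclip_fraction)
    keep = ~(multi | clip5 | clipfrac)
    report.multi_aligned = int(multi.sum())
    report.softclipped_5prime = int(clip5.sum())
    report.softclipped_fraction = int(clipfrac.sum())
    report.kept = int(keep.sum())
    return tags[keep].reset_index(drop=True), report


def internal_counts(
    tags: pd.DataFrame,
    genome: GenomeModel,
    exclusion: int = DEFAULT_EXCLUSION,
    sample_column: str = "sample_id",
) -> pd.DataFrame:
    """Per-gene tag counts beyond the first ``exclusion`` bp of the gene body.

    A tag counts for a gene iff it lies on the gene's strand and its 5'
    position maps to a transcription-oriented offset in
    ``[exclusion, gene length)``.  Returns a genes x samples table.
    """
    samples = sorted(tags[sample_column].unique()) if len(tags) else []
    table = pd.DataFrame(
        0, index=[g.gene_id for g in genome.genes], columns=samples, dtype=int
    )
    by_chrom_strand = {
        key: sub for key, sub in tags.groupby(["chromosome", "strand"], sort=False)
    }
    for gene in genome.genes:
        sub = by_chrom_strand.get((gene.chromosome, gene.strand))
        if sub is None or sub.empty:
            continue
        rel = np.where(
            gene.strand == "+",
            sub["five_prime_position"].to_numpy() - gene.tss,
            gene.tss - sub["five_prime_position"].to_numpy(),
        )
        inside = (rel >= exclusion) & (rel < gene.length)
        if inside.any():
            hits = sub.loc[inside, sample_column].value_counts()
            for sample, n in hits.items():
                table.loc[gene.gene_id, sample] += int(n)
    table.index.name = "gene_id"
    return table


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors: median ratio to the per-gene geometric mean."""
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log = np.log(mat)
    finite = np.isfinite(log).all(axis=1)
    if finite.sum() == 0:
        raise ValueError("no gene has positive counts in every sample")
    ref = log[finite].mean(axis=1)
    factors = np.exp(np.median(log[finite] - ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def call_internal_initiation(
    counts: pd.DataFrame,
    conditions: dict[str, str],
    *,
    condition_a: str,
    condition_b: str,
    padj_threshold: float = 0.1,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """NB Wald test per gene between two conditions, BH-adjusted.

    ``conditions`` maps sample (column) to condition label; condition B is
    the strain suspected of gaining internal initiation.  Genes with zero
    counts in all samples are dropped from testing and reported with
    ``called = False``.  A gene is called iff ``log2_fold_change > 0`` and
    ``padj < padj_threshold``.
    """
    cols_a = [c for c in counts.columns if conditions.get(c) == condition_a]
    cols_b = [c for c in counts.columns if conditions.get(c) == condition_b]
    if not cols_a or not cols_b:
        raise ValueError("both conditions need at least one sample")
    sf = median_of_ratios(counts[cols_a + cols_b])
    nonzero = counts[cols_a + cols_b].sum(axis=1) > 0
    sub = counts.loc[nonzero]

    ka = sub[cols_a].to_numpy(dtype=float)
    kb = sub[cols_b].to_numpy(dtype=float)
    fa = np.broadcast_to(sf[cols_a].to_numpy(), ka.shape)
    fb = np.broadcast_to(sf[cols_b].to_numpy(), kb.shape)
    res = nb_wald_test(ka, kb, fa, fb, dispersion=dispersion)
    res.index = sub.index
    res["padj"] = benjamini_hochberg(res["wald_p"].to_numpy())
    res["called"] = (res["log2_fold_change"] > 0) & (res["padj"] < padj_threshold)

    out = res.reindex(counts.index)
    out["called"] = out["called"].fillna(False).astype(bool)
    out.index.name = "gene_id"
    return out
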