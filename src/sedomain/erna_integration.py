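"""Enhancer-RNA differential expression and eRNA-mRNA concordance.

eRNA abundance is supplied as a counts matrix over SED intervals (one row per
SED); differential expression delegates to the shared DE engine with the eRNA
significance gates (|log2FC| > 1.5, FDR < 0.05).  Each SED eRNA is annotated
with the gene whose TSS is closest to the SED center, the eRNA fold change is
propagated to every gene whose TSS lies within +-1.5 Mb of the eRNA interval
(mean over multiple contributing eRNAs), and the gene-level concordance
between eRNA and mRNA log2 fold changes is summarized with Kendall's tau-b.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .element_domains import Domain
from .expression_de import DEConfig, de_test
from .genomic_core import GeneAnnotation, GenomicInterval, distance_to_nearest

__all__ = [
    "erna_de",
    "annotate_closest_gene",
    "erna_to_genes",
    "kendall_tau",
    "erna_mrna_concordance",
]


def erna_de(
    erna_counts: pd.DataFrame,
    condition_labels: Sequence[str],
    seds: Sequence[Domain],
    cfg: DEConfig = DEConfig(),
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> pd.DataFrame:
    """Differential expression of SED eRNAs (rows keyed by sed_id)."""
    sed_ids = {d.domain_id for d in seds}
    orphans = sorted(set(erna_counts.index) - sed_ids)
    if orphans:
        raise ValueError(f"eRNA rows without a matching SED: {orphans[:10]}")
    return de_test(erna_counts, condition_labels, cfg, condition_a, condition_b)


def annotate_closest_gene(
    seds: Sequence[Domain], genes: Sequence[GeneAnnotation]
) -> dict[str, str]:
    """sed_id -> gene whose TSS is nearest the SED center (ties to smaller coord)."""
    if len(genes) == 0:
        raise ValueError("annotate_closest_gene requires a nonempty gene set")
    targets = [(g.chrom, g.tss, g.gene_id) for g in genes]
    queries = [(d.interval.chrom, d.center) for d in seds]
    nearest = distance_to_nearest(queries, targets)
    return {
        d.domain_id: gid for d, (_, gid) in zip(seds, nearest) if gid is not None
    }


def erna_to_genes(
    erna_de_results: pd.DataFrame,
    sed_intervals: Mapping[str, GenomicInterval],
    genes: Sequence[GeneAnnotation],
    window: int = 1_500_000,
) -> pd.DataFrame:
    """Mean eRNA log2fc per gene over all eRNAs within +-window of its TSS.

    A gene receives an eRNA's fold change when its TSS lies inside the eRNA
    interval expanded by ``window`` bp on each side.  Genes with no
    contributing eRNA are absent from the result.
    """
    tested = erna_de_results.dropna(subset=["log2fc"])
    entries = []  # (chrom, lo, hi, lfc) expanded intervals
    for _, row in tested.iterrows():
        iv = sed_intervals.get(row["feature_id"])
        if iv is None:
            continue
        entries.append((iv.chrom, max(0, iv.start - window), iv.end + window, row["log2fc"]))
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, lo, hi, lfc in entries:
        by_chrom.setdefault(chrom, []).append((lo, hi, lfc))
    rows = []
    for g in genes:
        contrib = [
            lfc for lo, hi, lfc in by_chrom.get(g.chrom, []) if lo <= g.tss < hi
        ]
        if contrib:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "erna_log2fc_mean": float(np.mean(contrib)),
                    "n_contributing_ernas": len(contrib),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "erna_log2fc_mean", "n_contributing_ernas"])


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall's tau-b with two-sided p.

    Exact pair-enumeration p for n <= 8 without ties; normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 2:
        raise ValueError("kendall_tau requires n >= 2")
    no_ties = np.unique(x).size == x.size and np.unique(y).size == y.size
    method = "exact" if (x.size <= 8 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def erna_mrna_concordance(
    gene_erna_lfc: pd.DataFrame, mrna_de: pd.DataFrame
) -> tuple[float, float, int]:
    """Gene-level Kendall tau between eRNA-derived and mRNA log2 fold changes.

    Computed over genes carrying both values; returns (tau, p, n).
    """
    merged = gene_erna_lfc.merge(
        mrna_de[["feature_id", "log2fc"]].rename(columns={"feature_id": "gene_id"}),
        on="gene_id",
    ).dropna(subset=["erna_log2fc_mean", "log2fc"])
    n = len(merged)
    if n < 2:
        raise ValueError("fewer than 2 genes carry both an eRNA and an mRNA log2fc")
    tau, p = kendall_tau(merged["erna_log2fc_mean"], merged["log2fc"])
    return tau, p, n
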