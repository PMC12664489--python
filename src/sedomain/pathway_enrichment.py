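"""Preranked gene-set enrichment and hypergeometric over-representation.

``preranked_gsea`` implements the classic running-sum enrichment score on a
ranking of genes by a statistic (here: log2 fold changes): genes are sorted
descending, hits increment the running sum proportionally to
``|statistic|^weight`` (normalized to 1 within the set), misses decrement by
``1/(N-n)``, and the ES is the maximum deviation from zero.  The null is
gene-label permutation at fixed set size; NES divides the ES by the mean
|null ES| of the same sign, and FDR follows the standard preranked NES-ratio
procedure.  ``hypergeom_enrich`` is the upper-tail hypergeometric test used
for GO-style term collections.
"""

from __future__ import annotations

from collections.abc import Mapping, Set
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression_de import bh_adjust

__all__ = [
    "GeneSetCollection",
    "GSEAResult",
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "preranked_gsea",
    "hypergeom_enrich",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe, with size filtering."""

    sets: dict[str, frozenset]
    universe: frozenset

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Set[str]],
        universe: Set[str],
        min_size: int = 5,
        max_size: int = 500,
    ) -> "GeneSetCollection":
        universe = frozenset(universe)
        kept: dict[str, frozenset] = {}
        for name in sorted(sets):
            members = frozenset(sets[name]) & universe
            if min_size <= len(members) <= max_size:
                kept[name] = members
        return cls(kept, universe)


@dataclass(frozen=True)
class GSEAResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr: float
    leading_edge: tuple[str, ...]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: set name, description, then member genes, tab-separated."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
            out[fields[0]] = set(fields[2:])
    return out


def write_gmt(sets: Mapping[str, Set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def _rank_genes(ranking: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    """Sort genes by statistic descending; ties break by gene id (deterministic)."""
    items = sorted(ranking.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in items]
    stat = np.asarray([s for _, s in items], dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("ranking statistics must be finite")
    return genes, stat


def _es_from_positions(
    hit_pos: np.ndarray, stat: np.ndarray, N: int, weight: float
) -> tuple[float, int]:
    """Enrichment score from sorted hit positions; returns (es, peak index)."""
    n = hit_pos.size
    w = np.abs(stat[hit_pos]) ** weight
    total = w.sum()
    if total == 0:  # all-zero statistics in the set: equal hit increments
        w = np.ones(n)
        total = float(n)
    hit_steps = w / total
    miss = 1.0 / (N - n)
    # the running sum rises only at hits and falls between them, so its
    # extremes occur right after a hit (maxima) or right before one (minima);
    # the final value is 0 by normalization
    cum_hits = np.cumsum(hit_steps)
    misses_before = hit_pos - np.arange(n)  # misses preceding each hit
    at_hit = cum_hits - misses_before * miss  # value right after hit i
    before_hit = at_hit - hit_steps  # value right before hit i
    lo = min(float(before_hit.min()), 0.0)
    hi = float(at_hit.max())
    if hi >= -lo:
        peak = int(np.argmax(at_hit))
        return hi, peak
    peak = int(np.argmin(before_hit))
    return lo, peak


def enrichment_score(
    ranking: Mapping[str, float],
    gene_set: Set[str],
    weight: float = 1.0,
) -> tuple[float, list[str]]:
    """ES of a gene set on a ranking, with its leading edge."""
    genes, stat = _rank_genes(ranking)
    members = set(gene_set) & set(genes)
    if not members or len(members) == len(genes):
        raise ValueError("gene set must be a nonempty proper subset of the universe")
    hit_pos = np.asarray(sorted(i for i, g in enumerate(genes) if g in members))
    es, peak = _es_from_positions(hit_pos, stat, len(genes), weight)
    if es >= 0:
        leading = [genes[i] for i in hit_pos[: peak + 1]]
    else:
        leading = [genes[i] for i in hit_pos[peak:]]
    return es, leading


def preranked_gsea(
    ranking: Mapping[str, float],
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    p = fraction of same-sign permutation ES at least as extreme as the
    observed ES; NES = ES / mean(|null ES| of the same sign); FDR compares the
    pooled null NES distribution against the observed NES values (standard
    NES-ratio procedure).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    genes, stat = _rank_genes(ranking)
    N = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    results = []
    null_nes_pos: list[float] = []
    null_nes_neg: list[float] = []
    obs_nes: list[float] = []
    for name, members in collection.sets.items():
        members = members & set(genes)
        if not members:
            continue
        hit_pos = np.asarray(sorted(gene_index[g] for g in members))
        n = hit_pos.size
        es, peak = _es_from_positions(hit_pos, stat, N, weight)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = np.sort(rng.choice(N, size=n, replace=False))
            null[i], _ = _es_from_positions(perm, stat, N, weight)
        same_sign = null >= 0 if es >= 0 else null <= 0
        n_same = max(int(same_sign.sum()), 1)
        p = float((np.abs(null[same_sign]) >= abs(es)).sum()) / n_same
        mean_same = float(np.abs(null[same_sign]).mean()) if same_sign.any() else np.nan
        nes = es / mean_same if mean_same and mean_same > 0 else 0.0
        # normalize the null the same way for the FDR pool
        pos = null[null >= 0]
        neg = null[null < 0]
        if pos.size:
            null_nes_pos.extend((pos / pos.mean()).tolist())
        if neg.size:
            null_nes_neg.extend((neg / np.abs(neg).mean()).tolist())
        if es >= 0:
            leading = [genes[i] for i in hit_pos[: peak + 1]]
        else:
            leading = [genes[i] for i in hit_pos[peak:]]
        obs_nes.append(nes)
        results.append(
            {
                "set_name": name,
                "size": n,
                "es": es,
                "nes": nes,
                "p_value": p,
                "leading_edge": ",".join(leading),
            }
        )

    # NES-ratio FDR
    obs = np.asarray(obs_nes)
    npos, nneg = np.asarray(null_nes_pos), np.asarray(null_nes_neg)
    fdrs = []
    for nes in obs:
        if nes >= 0:
            frac_null = (npos >= nes).mean() if npos.size else 1.0
            frac_obs = (obs[obs >= 0] >= nes).mean() if (obs >= 0).any() else 1.0
        else:
            frac_null = (nneg <= nes).mean() if nneg.size else 1.0
            frac_obs = (obs[obs < 0] <= nes).mean() if (obs < 0).any() else 1.0
        fdrs.append(min(1.0, float(frac_null / max(frac_obs, 1e-12))))
    df = pd.DataFrame(results)
    if len(df):
        df["fdr"] = fdrs
    return df


def hypergeom_enrich(
    query: Set[str],
    terms: GeneSetCollection,
    background: Set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a query set per term.

    For each term: N = |background|, K = |term & background|, n = |query|,
    k = |query & term|, p = P(X >= k); BH adjustment across terms.
    """
    background = set(background)
    stray = set(query) - background
    if stray:
        raise ValueError(f"query genes outside the background: {sorted(stray)[:10]}")
    N, n = len(background), len(query)
    rows = []
    for name, members in terms.sets.items():
        K = len(members & background)
        k = len(set(query) & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": name, "k": k, "K": K, "n": n, "N": N, "p_value": min(1.0, p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_adjust(df["p_value"].to_numpy())
    return df
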