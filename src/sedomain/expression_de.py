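"""Minimal differential-expression stage for mRNA and eRNA count matrices.

Counts are normalized by median-of-ratios size factors, log2-transformed with
a pseudocount, and tested per feature with a two-sided Welch t-test; p-values
are Benjamini-Hochberg adjusted per contrast.  This engine is a documented,
self-contained substitute for a negative-binomial GLM package: the downstream
stages consume only ``log2fc`` and ``p_adj``, and an ingest mode accepts
externally produced DE tables bit-exactly for users who prefer their own
engine.

Significance gates follow the study conventions: ``|log2FC| > 1`` for genes,
``|log2FC| > 1.5`` for eRNAs, FDR < 0.05, all strict inequalities.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEConfig",
    "median_ratio_normalize",
    "de_test",
    "bh_adjust",
    "significant_set",
    "read_de_table",
    "write_de_table",
]

DE_COLUMNS = ["feature_id", "mean_expression", "log2fc", "p_value", "p_adj"]


@dataclass(frozen=True)
class DEConfig:
    lfc_threshold_gene: float = 1.0
    lfc_threshold_erna: float = 1.5
    fdr: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.lfc_threshold_gene <= 0 or self.lfc_threshold_erna <= 0:
            raise ValueError("log2FC thresholds must be > 0")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def median_ratio_normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    Size factor of sample j is the median over features positive in every
    sample of ``count_ij / geometric_mean_i``.  Raises if no feature is
    positive in all samples.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    if x.shape[1] == 1:
        factors = pd.Series([1.0], index=counts.columns)
        return factors, counts.astype(float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in every sample; add a pseudocount "
            "before normalization"
        )
    ref = x[all_pos]
    geo = np.exp(np.mean(np.log(ref), axis=1))
    factors = np.median(ref / geo[:, None], axis=0)
    sf = pd.Series(factors, index=counts.columns)
    return sf, counts / sf


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    counts: pd.DataFrame,
    condition_labels: Sequence[str],
    cfg: DEConfig = DEConfig(),
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> pd.DataFrame:
    """Per-feature log2 fold change (A over B) with Welch p and BH adjustment.

    ``condition_labels`` aligns with the count columns.  By default the two
    conditions are taken in sorted order (A = first).  Features with zero
    counts in every sample are excluded from testing and returned with NaN
    statistics in a ``tested`` = False row.
    """
    labels = np.asarray(condition_labels)
    if len(labels) != counts.shape[1]:
        raise ValueError("one condition label per sample column is required")
    uniq = sorted(set(labels))
    if condition_a is None or condition_b is None:
        if len(uniq) != 2:
            raise ValueError(f"expected exactly 2 conditions, got {uniq}")
        condition_a, condition_b = uniq
    for cond in (condition_a, condition_b):
        if (labels == cond).sum() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")

    _, norm = median_ratio_normalize(counts)
    x = np.log2(norm.to_numpy(dtype=float) + cfg.pseudocount)
    in_a = labels == condition_a
    in_b = labels == condition_b
    tested = counts.to_numpy().sum(axis=1) > 0

    lfc = x[:, in_a].mean(axis=1) - x[:, in_b].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(x[:, in_a], x[:, in_b], axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: identical values -> no evidence, p = 1
    p[np.isnan(p)] = 1.0

    out = pd.DataFrame(
        {
            "feature_id": counts.index,
            "mean_expression": norm.to_numpy().mean(axis=1),
            "log2fc": lfc,
            "p_value": p,
            "tested": tested,
        }
    )
    out.loc[~out["tested"], ["log2fc", "p_value"]] = np.nan
    p_adj = np.full(len(out), np.nan)
    mask = out["tested"].to_numpy()
    p_adj[mask] = bh_adjust(out.loc[mask, "p_value"].to_numpy())
    out["p_adj"] = p_adj
    return out


def significant_set(
    results: pd.DataFrame,
    direction: str = "both",
    lfc_threshold: float = 1.0,
    fdr: float = 0.05,
) -> set[str]:
    """Features with ``p_adj < fdr`` and log2fc strictly beyond the threshold.

    ``direction`` is ``up``, ``down`` or ``both``; a threshold of 0 reproduces
    p-only gates.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    df = results.dropna(subset=["p_adj", "log2fc"])
    sig = df["p_adj"] < fdr
    if direction == "up":
        sig &= df["log2fc"] > lfc_threshold
    elif direction == "down":
        sig &= df["log2fc"] < -lfc_threshold
    else:
        sig &= df["log2fc"].abs() > lfc_threshold
    return set(df.loc[sig, "feature_id"])


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Ingest an externally produced DE table, preserving every value bit-exactly."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE columns {missing}")
    if "tested" not in df.columns:
        df["tested"] = True
    return df


def write_de_table(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
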