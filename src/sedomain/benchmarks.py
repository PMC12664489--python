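"""Recovery and calibration harnesses over the synthetic-data generator.

Each function plants a known effect (or none), runs the corresponding
analysis stage end to end, and scores recovery against the generator's truth
tables.  They back both the validation test suite and the reproduction
script, and are useful for re-calibrating after parameter changes.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import replace

import numpy as np
import pandas as pd

from . import core_set as core_set_mod
from . import erna_integration, sed_distance, tf_enrichment
from .element_domains import Domain, call_elements, pool_domains
from .expression_de import DEConfig, de_test, significant_set
from .synthetic_data import SimConfig, simulate_cohort, simulate_null_tf_regions

__all__ = [
    "cohort_domains",
    "planted_se_recovery",
    "tf_recovery_rate",
    "null_tf_significant_fraction",
    "distance_bin_table",
    "distance_decay_success",
    "null_distance_significant_fraction",
    "core_set_precision_recall",
    "tau_by_coupling",
]


def cohort_domains(cohort) -> list[Domain]:
    """Call elements per sample and pool super-enhancer domains."""
    elements = {
        sid: call_elements(cohort.peaks[sid], cohort.genes)
        for sid in sorted(cohort.peaks)
    }
    return pool_domains(elements, "SE", cohort.sample_sheet)


def planted_se_recovery(cohort, domains: Sequence[Domain] | None = None) -> float:
    """Fraction of planted SEs inside a recovered SED of matching specificity."""
    domains = cohort_domains(cohort) if domains is None else domains
    by_spec: dict[str, list] = {}
    for d in domains:
        by_spec.setdefault(d.specificity, []).append(d.interval)
    ok = 0
    for _, row in cohort.sed_truth.iterrows():
        for iv in by_spec.get(row["specificity"], []):
            if iv.chrom == row["chrom"] and iv.start <= row["start"] and iv.end >= row["end"]:
                ok += 1
                break
    return ok / len(cohort.sed_truth)


def tf_recovery_rate(
    config_for_seed: Callable[[int], SimConfig], seeds: Sequence[int]
) -> float:
    """Fraction of planted TFs recovered (delta > 0, Bonferroni p <= 0.05)."""
    hits = total = 0
    for seed in seeds:
        cohort = simulate_cohort(config_for_seed(seed))
        domains = cohort_domains(cohort)
        catalog = tf_enrichment.prepare_cistrome(cohort.cistrome, 10_000)
        table = tf_enrichment.tumor_normal_enrichment(
            domains, catalog, cohort.genome
        ).set_index("tf")
        for tf in cohort.enriched_tfs:
            total += 1
            if tf in table.index:
                row = table.loc[tf]
                if row["significant_T"] and row["delta"] > 0:
                    hits += 1
    return hits / total


def null_tf_significant_fraction(config: SimConfig, n_tfs: int = 200) -> float:
    """Fraction of null (uniformly placed) TFs called significant on T-SEDs."""
    cohort = simulate_cohort(config)
    domains = [d for d in cohort_domains(cohort) if d.specificity == "T"]
    null_cistrome = simulate_null_tf_regions(config, n_tfs=n_tfs)
    catalog = tf_enrichment.prepare_cistrome(null_cistrome, 10_000)
    records = tf_enrichment.enrich_tfs(domains, catalog, cohort.genome)
    if not records:
        return 0.0
    return sum(r.significant for r in records) / len(records)


def distance_bin_table(cohort, mrna_de: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assign genes to recovered SEDs and run the binned T-vs-N Wilcoxon tests."""
    domains = cohort_domains(cohort)
    if mrna_de is None:
        mrna_de = de_test(
            cohort.mrna_counts, cohort.mrna_labels, DEConfig(),
            condition_a="tumor", condition_b="normal",
        )
    assignments = sed_distance.assign_genes(cohort.genes, domains, mrna_de)
    return sed_distance.bin_and_test(assignments)


def distance_decay_success(config: SimConfig, fdr: float = 0.05) -> bool:
    """True when at least one bin below 0.5 Mb is significant and no bin
    beyond 1.1 Mb is, matching a planted effect that dies at 1 Mb."""
    bins = distance_bin_table(simulate_cohort(config))
    near = bins[(bins["bin_hi"] <= 500_000) & bins["p_adj"].notna()]
    far = bins[(bins["bin_lo"] >= 1_100_000) & bins["p_adj"].notna()]
    near_hit = bool((near["p_adj"] < fdr).any())
    far_clean = not bool((far["p_adj"] < fdr).any())
    return near_hit and far_clean


def null_distance_significant_fraction(
    config_for_seed: Callable[[int], SimConfig], seeds: Sequence[int]
) -> float:
    """Fraction of testable bins with p_adj < 0.05 when no effect is planted."""
    sig = testable = 0
    for seed in seeds:
        cfg = config_for_seed(seed)
        if cfg.effect_lfc != 0.0:
            cfg = replace(cfg, effect_lfc=0.0)
        bins = distance_bin_table(simulate_cohort(cfg))
        tested = bins["p_adj"].notna()
        testable += int(tested.sum())
        sig += int((bins.loc[tested, "p_adj"] < 0.05).sum())
    return sig / testable if testable else 0.0


def core_set_precision_recall(config: SimConfig) -> tuple[float, float, int]:
    """Precision/recall of the three-way intersection against planted core genes."""
    cohort = simulate_cohort(config)
    domains = cohort_domains(cohort)
    mrna_de = de_test(cohort.mrna_counts, cohort.mrna_labels, DEConfig(),
                      condition_a="tumor", condition_b="normal")
    up = significant_set(mrna_de, "up", lfc_threshold=0.0, fdr=0.05)
    near = core_set_mod.near_tsed_genes(cohort.genes, domains, 2_000_000)
    downs = [
        significant_set(
            de_test(cohort.jq1_counts[line], cohort.jq1_labels[line], DEConfig(),
                    condition_a="JQ1", condition_b="DMSO"),
            "down", lfc_threshold=0.0, fdr=0.05,
        )
        for line in sorted(cohort.jq1_counts)
    ]
    result = core_set_mod.intersect_core(up, near, downs[0], downs[1])
    truth = set(cohort.gene_truth.loc[cohort.gene_truth["is_core"], "gene_id"])
    tp = len(result.core_genes & truth)
    precision = tp / len(result.core_genes) if result.core_genes else 0.0
    recall = tp / len(truth) if truth else 0.0
    return precision, recall, len(result.core_genes)


def tau_by_coupling(
    base_config: SimConfig, couplings: Sequence[float] = (0.2, 0.5, 0.8)
) -> list[float]:
    """Gene-level eRNA-mRNA Kendall tau at several coupling strengths,
    holding the seed (and thus every other component) fixed."""
    taus = []
    for coupling in couplings:
        cohort = simulate_cohort(replace(base_config, erna_coupling=coupling))
        mrna_de = de_test(cohort.mrna_counts, cohort.mrna_labels, DEConfig(),
                          condition_a="tumor", condition_b="normal")
        doms = [Domain(iv, "SED", "C", frozenset(), domain_id=sid)
                for sid, iv in cohort.truth_sed_intervals.items()]
        er = erna_integration.erna_de(
            cohort.erna_counts, cohort.erna_labels, doms, DEConfig(),
            condition_a="tumor", condition_b="normal",
        )
        gene_level = erna_integration.erna_to_genes(er, cohort.truth_sed_intervals, cohort.genes)
        tau, _, _ = erna_integration.erna_mrna_concordance(gene_level, mrna_de)
        taus.append(tau)
    return taus
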