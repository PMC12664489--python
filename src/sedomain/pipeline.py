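"""End-to-end orchestration: simulate -> elements -> domains -> enrichment ->
DE -> distance -> eRNA -> core set -> pathways, with a manifest of every
artifact.

``run_all`` executes the stages in dependency order against a synthetic
cohort (the packaged fixture is the generator at its default seed), writing
every intermediate table in the same flat formats the standalone subcommands
consume, plus a JSON manifest with the SHA-256 of each output so reruns can
be checked for reproducibility.  Each stage is also importable and
individually invocable with identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_set as core_set_mod
from . import erna_integration, pathway_enrichment, sed_distance, tf_enrichment
from .element_domains import Domain, ElementConfig, call_elements, pool_domains
from .expression_de import DEConfig, de_test, significant_set, write_de_table
from .genomic_core import GenomicInterval, write_bed
from .synthetic_data import SimConfig, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_all", "tf_expression_join", "read_domains", "write_domains"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 17
    outdir: str = "sedomain_run"
    sim: SimConfig = field(default_factory=SimConfig)
    promoter_window: int = 2500
    stitch_distance: int = 0
    pool_gap: int = 0
    cistrome_merge_distance: int = 10_000
    shade_distances: tuple[int, ...] = (10_000, 100_000)
    lfc_threshold_gene: float = 1.0
    lfc_threshold_erna: float = 1.5
    fdr: float = 0.05
    bin_width: int = 100_000
    max_distance: int = 2_000_000
    erna_window: int = 1_500_000
    near_window: int = 2_000_000
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    gsea_min_size: int = 5
    gsea_max_size: int = 500

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim = SimConfig(**{**asdict(self.sim), "seed": self.seed})
        self.shade_distances = tuple(self.shade_distances)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_domains(domains: list[Domain], path: str | Path) -> None:
    """BED-like: chrom, start, end, domain_id, specificity, supporters (comma list)."""
    with open(path, "w") as fh:
        for d in domains:
            sup = ",".join(sorted(d.supporting_samples)) or "."
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t"
                f"{d.domain_id}\t{d.specificity}\t{sup}\n"
            )


def read_domains(path: str | Path, category: str) -> list[Domain]:
    out: list[Domain] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields")
            chrom, start, end, dom_id, spec, sup = fields
            supporters = frozenset() if sup == "." else frozenset(sup.split(","))
            out.append(
                Domain(
                    GenomicInterval(chrom, int(start), int(end)),
                    category, spec, supporters, domain_id=dom_id,
                )
            )
    return out


def tf_expression_join(
    enrichment: pd.DataFrame,
    de_tables: dict[str, pd.DataFrame],
    alias: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Expression matrix of tumor-leaning TFs across contrasts, with stars.

    Rows are TFs significant in the tumor test with delta > 0; columns come
    in pairs ``<contrast>_log2fc`` / ``<contrast>_stars`` where stars encode
    FDR-adjusted significance (* < 0.05, ** < 0.01, *** < 0.001).  TF names
    unresolvable to a gene id in every DE table are dropped with a log entry.
    """
    alias = alias or {}
    tumor_tfs = enrichment[(enrichment["significant_T"]) & (enrichment["delta"] > 0)]
    rows = []
    for _, erow in tumor_tfs.iterrows():
        tf = erow["tf"]
        gene = alias.get(tf, tf)
        row: dict[str, object] = {"tf": tf, "gene_id": gene}
        found = False
        for contrast, de in de_tables.items():
            hit = de[de["feature_id"] == gene]
            if hit.empty:
                row[f"{contrast}_log2fc"] = np.nan
                row[f"{contrast}_stars"] = ""
                continue
            found = True
            padj = float(hit["p_adj"].iloc[0])
            stars = "***" if padj < 0.001 else "**" if padj < 0.01 else "*" if padj < 0.05 else ""
            row[f"{contrast}_log2fc"] = float(hit["log2fc"].iloc[0])
            row[f"{contrast}_stars"] = stars
        if found:
            rows.append(row)
        else:
            logger.info("TF %s not resolvable in any DE table; dropped", tf)
    cols = ["tf", "gene_id"]
    for contrast in de_tables:
        cols += [f"{contrast}_log2fc", f"{contrast}_stars"]
    return pd.DataFrame(rows, columns=cols)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic cohort; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    def record(stage: str, outputs: dict[str, Path], params: dict) -> None:
        manifest[stage] = {
            "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                        for k, p in outputs.items() if Path(p).is_file()},
            "params": params,
            "status": "ok",
        }

    # stage 1: simulate ------------------------------------------------------
    cohort = simulate_cohort(config.sim)
    sim_paths = write_cohort(cohort, outdir / "inputs")
    record("simulate", {k: v for k, v in sim_paths.items()}, {"seed": config.seed})

    # stage 2: call elements per sample --------------------------------------
    el_cfg = ElementConfig(config.promoter_window, config.stitch_distance)
    elements = {
        sid: call_elements(cohort.peaks[sid], cohort.genes, el_cfg)
        for sid in sorted(cohort.peaks)
    }
    el_dir = outdir / "elements"
    el_dir.mkdir(exist_ok=True)
    el_paths = {}
    for sid, els in elements.items():
        ivs = [
            GenomicInterval(e.interval.chrom, e.interval.start, e.interval.end,
                            name=e.element_class,
                            score=e.se_score if e.se_score is not None else None)
            for e in els
        ]
        p = el_dir / f"{sid}.elements.bed"
        write_bed(ivs, p)
        el_paths[sid] = p
    record("call_elements", el_paths, {"promoter_window": config.promoter_window,
                                       "stitch_distance": config.stitch_distance})

    # stage 3: pool domains ---------------------------------------------------
    domains: dict[str, list[Domain]] = {}
    dom_paths = {}
    for cat in ("P", "E", "SE"):
        doms = pool_domains(elements, cat, cohort.sample_sheet, config.pool_gap)
        cat_name = {"P": "PD", "E": "ED", "SE": "SED"}[cat]
        domains[cat_name] = doms
        p = outdir / f"domains_{cat_name}.bed"
        write_domains(doms, p)
        dom_paths[cat_name] = p
    record("build_domains", dom_paths, {"pool_gap": config.pool_gap})

    # stage 4: TF enrichment per category -------------------------------------
    cistrome = tf_enrichment.prepare_cistrome(
        cohort.cistrome, config.cistrome_merge_distance
    )
    enr_paths = {}
    enrichment_tables: dict[str, pd.DataFrame] = {}
    for cat_name, doms in domains.items():
        df = tf_enrichment.tumor_normal_enrichment(
            doms, cistrome, cohort.genome, config.shade_distances
        )
        enrichment_tables[cat_name] = df
        p = outdir / f"tf_enrichment_{cat_name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        enr_paths[cat_name] = p
    record("tf_enrich", enr_paths, {"D_values": list(config.shade_distances),
                                    "merge_distance": config.cistrome_merge_distance})

    # stage 5: differential expression ----------------------------------------
    de_cfg = DEConfig(config.lfc_threshold_gene, config.lfc_threshold_erna, config.fdr)
    mrna_de = de_test(cohort.mrna_counts, cohort.mrna_labels, de_cfg,
                      condition_a="tumor", condition_b="normal")
    de_paths = {"tumor_vs_normal": outdir / "de_tumor_vs_normal.tsv"}
    write_de_table(mrna_de, de_paths["tumor_vs_normal"])
    jq1_de: dict[str, pd.DataFrame] = {}
    for line, counts in sorted(cohort.jq1_counts.items()):
        jq1_de[line] = de_test(counts, cohort.jq1_labels[line], de_cfg,
                               condition_a="JQ1", condition_b="DMSO")
        p = outdir / f"de_jq1_vs_dmso_{line}.tsv"
        write_de_table(jq1_de[line], p)
        de_paths[f"jq1_{line}"] = p
    record("de", de_paths, {"fdr": config.fdr, "engine": "median-ratios + Welch"})

    # stage 6: SED distance analysis ------------------------------------------
    assignments = sed_distance.assign_genes(
        cohort.genes, domains["SED"], mrna_de, config.max_distance, config.fdr
    )
    bins = sed_distance.bin_and_test(assignments, config.bin_width, config.max_distance)
    p_bins = outdir / "sed_distance_bins.tsv"
    bins.to_csv(p_bins, sep="\t", index=False)
    assign_df = pd.DataFrame([asdict(a) for a in assignments])
    p_assign = outdir / "gene_sed_assignments.tsv"
    assign_df.to_csv(p_assign, sep="\t", index=False)
    record("distance", {"bins": p_bins, "assignments": p_assign},
           {"bin_width": config.bin_width, "max_distance": config.max_distance})

    # stage 7: eRNA integration ------------------------------------------------
    sed_domains = domains["SED"]
    # eRNA counts are keyed by the generator's truth SED intervals
    erna = erna_integration.erna_de(
        cohort.erna_counts, cohort.erna_labels,
        [Domain(iv, "SED", "C", frozenset(), domain_id=sid)
         for sid, iv in cohort.truth_sed_intervals.items()],
        de_cfg, condition_a="tumor", condition_b="normal",
    )
    closest = erna_integration.annotate_closest_gene(
        [Domain(iv, "SED", "C", frozenset(), domain_id=sid)
         for sid, iv in cohort.truth_sed_intervals.items()],
        cohort.genes,
    )
    erna["closest_gene"] = erna["feature_id"].map(closest)
    p_erna = outdir / "erna_de.tsv"
    erna.to_csv(p_erna, sep="\t", index=False)
    gene_erna = erna_integration.erna_to_genes(
        erna, cohort.truth_sed_intervals, cohort.genes, config.erna_window
    )
    p_gene_erna = outdir / "gene_erna_lfc.tsv"
    gene_erna.to_csv(p_gene_erna, sep="\t", index=False)
    tau, tau_p, tau_n = erna_integration.erna_mrna_concordance(gene_erna, mrna_de)
    p_tau = outdir / "erna_mrna_concordance.tsv"
    pd.DataFrame([{"kendall_tau": tau, "p_value": tau_p, "n_genes": tau_n}]).to_csv(
        p_tau, sep="\t", index=False
    )
    record("erna", {"erna_de": p_erna, "gene_erna": p_gene_erna, "tau": p_tau},
           {"window": config.erna_window})

    # stage 8: core set ----------------------------------------------------------
    up_tumor = significant_set(mrna_de, "up", lfc_threshold=0.0, fdr=config.fdr)
    near = core_set_mod.near_tsed_genes(cohort.genes, sed_domains, config.near_window)
    lines = sorted(jq1_de)
    down1 = significant_set(jq1_de[lines[0]], "down", lfc_threshold=0.0, fdr=config.fdr)
    down2 = significant_set(jq1_de[lines[1]], "down", lfc_threshold=0.0, fdr=config.fdr)
    core = core_set_mod.intersect_core(up_tumor, near, down1, down2)
    background = {g.gene_id for g in cohort.genes}
    fisher = core_set_mod.core_overlap_tests(
        up_tumor, near, down1, down2, background, line_names=(lines[0], lines[1])
    )
    p_core = outdir / "core_genes.tsv"
    pd.DataFrame({"gene_id": sorted(core.core_genes)}).to_csv(p_core, sep="\t", index=False)
    p_venn = outdir / "core_venn_counts.tsv"
    pd.DataFrame([core.venn_counts]).to_csv(p_venn, sep="\t", index=False)
    p_fisher = outdir / "core_fisher.tsv"
    fisher.to_csv(p_fisher, sep="\t", index=False)
    # TF expression join (synthetic alias: TFnnn -> GENE000nn, for exercise)
    alias = {tf: f"GENE{int(tf[2:]):05d}" for tf in enrichment_tables["SED"]["tf"]}
    de_named = {"tumor_vs_normal": mrna_de, **{f"jq1_{l}": jq1_de[l] for l in lines}}
    tf_expr = tf_expression_join(enrichment_tables["SED"], de_named, alias)
    p_tfexpr = outdir / "tf_expression_matrix.tsv"
    tf_expr.to_csv(p_tfexpr, sep="\t", index=False)
    record("core_set", {"core": p_core, "venn": p_venn, "fisher": p_fisher,
                        "tf_expression": p_tfexpr},
           {"near_window": config.near_window})

    # stage 9: pathway enrichment -------------------------------------------------
    ranking = dict(zip(mrna_de["feature_id"], mrna_de["log2fc"].fillna(0.0)))
    collection = pathway_enrichment.GeneSetCollection.from_sets(
        cohort.gene_sets, set(ranking), config.gsea_min_size, config.gsea_max_size
    )
    gsea = pathway_enrichment.preranked_gsea(
        ranking, collection, config.gsea_n_perm, seed=config.seed,
        weight=config.gsea_weight,
    )
    p_gsea = outdir / "gsea_tumor_vs_normal.tsv"
    gsea.to_csv(p_gsea, sep="\t", index=False)
    go = pathway_enrichment.hypergeom_enrich(core.core_genes, collection, background)
    p_go = outdir / "core_go_enrichment.tsv"
    go.to_csv(p_go, sep="\t", index=False)
    record("pathways", {"gsea": p_gsea, "go": p_go},
           {"n_perm": config.gsea_n_perm, "weight": config.gsea_weight})

    manifest_path = outdir / "manifest.json"
    tmp = manifest_path.with_suffix(".json.tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    tmp.replace(manifest_path)
    return manifest
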