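"""Synthetic cohort generator with planted, recoverable effects.

The generator emulates the statistical structure of an H3K27ac super-enhancer
study at desk scale: per-sample peak sets whose enhancer scores follow a
heavy-tailed (log-normal) distribution with a planted super-enhancer upper
tail; tumor-specific, normal-specific and shared super-enhancer domains; a
cistrome of per-TF binding regions with a density enrichment planted inside
tumor-specific domains for chosen TFs; negative-binomial mRNA counts whose
tumor/normal log2 fold changes decay linearly with the distance of the TSS to
the nearest planted SED (positive near T-SEDs, mirrored negative near
N-SEDs, reaching zero at ``decay_range_bp``); a JQ1 perturbation that
reverses the planted effect of a designated core-gene subset; and eRNA counts
over the planted SED intervals whose fold changes correlate with the proximal
mRNA response with tunable strength.

Every planted quantity is recorded in truth tables so recovery can be scored.
All randomness flows from a single seed through independent child streams per
component, so changing e.g. ``erna_coupling`` leaves the peaks, cistrome, and
mRNA counts untouched.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .element_domains import Peak
from .genomic_core import (
    GeneAnnotation,
    GenomeTable,
    GenomicInterval,
    write_bed,
    write_chrom_sizes,
    write_counts,
    write_gene_table,
)
from .pathway_enrichment import write_gmt

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_null_tf_regions",
    "planted_lfc",
    "write_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the study's structure where it states one (2 tumor + 2
    normal ChIP samples; 47 tumor / 25 normal RNA samples; 2 JQ1-treated cell
    lines; planted effects reaching zero at ~1 Mb; 3x planted TF binding
    density) and desk-scale choices elsewhere (genome size, gene and domain
    counts), documented in the methods note.
    """

    seed: int = 17
    n_chrom: int = 5
    chrom_length: int = 40_000_000
    n_genes: int = 2000
    n_samples_tumor: int = 2
    n_samples_normal: int = 2
    n_rna_tumor: int = 47
    n_rna_normal: int = 25
    n_cell_lines: int = 2
    n_cell_reps: int = 8
    n_tfs: int = 40
    n_enriched_tfs: int = 5
    tf_density_fold: float = 3.0
    tf_regions_per_tf: int = 2000
    n_sed_t: int = 60
    n_sed_n: int = 60
    n_sed_c: int = 30
    n_core_genes: int = 50
    effect_lfc: float = 2.0
    decay_range_bp: int = 1_000_000
    nb_dispersion: float = 0.05
    mean_expression: float = 100.0
    erna_coupling: float = 0.7
    jq1_reversal_fraction: float = 0.8
    # background structure
    n_background_enhancers: int = 400
    n_promoter_peaks: int = 250
    background_lfc_sd: float = 0.30
    jq1_background_lfc_sd: float = 0.25
    erna_noise_sd: float = 0.8
    erna_mean_expression: float = 40.0
    library_size_sd: float = 0.3  # log-normal sigma: ~ +-30% library sizes

    def __post_init__(self) -> None:
        counts = (
            self.n_chrom, self.n_genes, self.n_samples_tumor, self.n_samples_normal,
            self.n_rna_tumor, self.n_rna_normal, self.n_cell_lines, self.n_cell_reps,
            self.n_tfs, self.n_enriched_tfs, self.tf_regions_per_tf,
            self.n_sed_t, self.n_sed_n, self.n_sed_c, self.n_core_genes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all count parameters must be >= 0")
        if not 0 <= self.jq1_reversal_fraction <= 1:
            raise ValueError("jq1_reversal_fraction must be in [0, 1]")
        if self.decay_range_bp > 2_000_000:
            raise ValueError("decay_range_bp must be <= 2,000,000")
        if self.decay_range_bp <= 0:
            raise ValueError("decay_range_bp must be > 0")
        if self.n_enriched_tfs > self.n_tfs:
            raise ValueError("n_enriched_tfs cannot exceed n_tfs")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class SyntheticCohort:
    config: SimConfig
    genome: GenomeTable
    genes: list[GeneAnnotation]
    sample_sheet: dict[str, str]  # ChIP sample -> tumor | normal
    peaks: dict[str, list[Peak]]
    cistrome: dict[str, list[GenomicInterval]]
    mrna_counts: pd.DataFrame
    mrna_labels: list[str]
    jq1_counts: dict[str, pd.DataFrame]  # cell line -> counts
    jq1_labels: dict[str, list[str]]
    erna_counts: pd.DataFrame
    erna_labels: list[str]
    gene_sets: dict[str, set[str]]
    # truth tables
    sed_truth: pd.DataFrame  # sed_id, chrom, start, end, specificity
    gene_truth: pd.DataFrame  # gene_id, planted_lfc, nearest spec/dist, is_core
    enriched_tfs: list[str]
    erna_truth: pd.DataFrame  # sed_id, true_lfc
    truth_sed_intervals: dict[str, GenomicInterval] = field(default_factory=dict)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.maximum(mean, 1e-8)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _place_seds(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Planted SED intervals: one per evenly spaced slot with jitter, shuffled labels."""
    total = cfg.n_sed_t + cfg.n_sed_n + cfg.n_sed_c
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    per = np.full(cfg.n_chrom, total // cfg.n_chrom)
    per[: total % cfg.n_chrom] += 1
    rows = []
    idx = 0
    labels = ["T"] * cfg.n_sed_t + ["N"] * cfg.n_sed_n + ["C"] * cfg.n_sed_c
    order = rng.permutation(total)
    for chrom, k in zip(chroms, per):
        if k == 0:
            continue
        slot = cfg.chrom_length // (k + 1)
        for j in range(k):
            center = (j + 1) * slot + int(rng.integers(-slot // 10, slot // 10 + 1))
            length = int(rng.integers(20_000, 40_001))
            start = max(0, center - length // 2)
            end = min(cfg.chrom_length, start + length)
            rows.append(
                {
                    "sed_id": f"TRUESED{idx + 1:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "specificity": labels[order[idx]],
                }
            )
            idx += 1
    return pd.DataFrame(rows, columns=["sed_id", "chrom", "start", "end", "specificity"])


def _place_genes(
    cfg: SimConfig, rng: np.random.Generator, sed_truth: pd.DataFrame
) -> tuple[list[GeneAnnotation], list[str]]:
    """Uniform TSSs kept clear of planted SEDs, plus core genes seeded near T-SEDs."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    sed_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _, row in sed_truth.iterrows():
        sed_by_chrom[row["chrom"]].append((row["start"] - 5000, row["end"] + 5000))

    def clear_of_seds(chrom: str, pos: int) -> bool:
        return all(not (lo <= pos < hi) for lo, hi in sed_by_chrom[chrom])

    genes: list[tuple[str, int, str]] = []
    t_seds = sed_truth[sed_truth["specificity"] == "T"].reset_index(drop=True)
    core_ids: list[str] = []
    n_core = min(cfg.n_core_genes, cfg.n_genes) if len(t_seds) else 0
    for i in range(n_core):
        row = t_seds.iloc[i % len(t_seds)]
        center = (row["start"] + row["end"]) // 2
        half = (row["end"] - row["start"]) // 2
        pos = min(cfg.chrom_length - 1, center + half + 6000)
        for _ in range(100):
            cand = center + int(rng.integers(half + 6000, 100_001)) * int(rng.choice([-1, 1]))
            if 0 <= cand < cfg.chrom_length and clear_of_seds(row["chrom"], cand):
                pos = cand
                break
        genes.append((row["chrom"], pos, "core"))
    for _ in range(cfg.n_genes - n_core):
        chrom = chroms[int(rng.integers(cfg.n_chrom))]
        pos = int(rng.integers(cfg.chrom_length))
        for _ in range(100):
            if clear_of_seds(chrom, pos):
                break
            chrom = chroms[int(rng.integers(cfg.n_chrom))]
            pos = int(rng.integers(cfg.chrom_length))
        genes.append((chrom, pos, "bg"))

    strands = rng.choice(["+", "-"], size=len(genes))
    order = sorted(range(len(genes)), key=lambda i: (genes[i][0], genes[i][1]))
    annotations = []
    for rank, i in enumerate(order):
        chrom, pos, kind = genes[i]
        gid = f"GENE{rank + 1:05d}"
        annotations.append(GeneAnnotation(gid, chrom, str(strands[i]), pos))
        if kind == "core":
            core_ids.append(gid)
    return annotations, sorted(core_ids)


def _make_peaks(
    cfg: SimConfig,
    rng: np.random.Generator,
    genes: Sequence[GeneAnnotation],
    sed_truth: pd.DataFrame,
) -> tuple[dict[str, str], dict[str, list[Peak]]]:
    """Per-sample promoter peaks, background enhancers, and planted SE peak clusters.

    Background enhancer signals are log-normal (heavy-tailed, convex
    rank-score curve); planted SE peaks are drawn from a far upper tail so
    their summed score clears the tangent cutoff.
    """
    sample_sheet = {
        **{f"tumor{i + 1}": "tumor" for i in range(cfg.n_samples_tumor)},
        **{f"normal{i + 1}": "normal" for i in range(cfg.n_samples_normal)},
    }
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    peaks: dict[str, list[Peak]] = {}
    for sample, condition in sample_sheet.items():
        plist: list[Peak] = []
        # promoter peaks on a random subset of genes
        n_prom = min(cfg.n_promoter_peaks, len(genes))
        for gi in rng.choice(len(genes), size=n_prom, replace=False):
            g = genes[int(gi)]
            half = int(rng.integers(500, 1500))
            start = max(0, g.tss - half)
            end = min(cfg.chrom_length, g.tss + half)
            signal = float(rng.lognormal(np.log(3.0), 0.5))
            plist.append(Peak(GenomicInterval(g.chrom, start, end), signal, sample))
        # background enhancers anywhere
        for _ in range(cfg.n_background_enhancers):
            chrom = chroms[int(rng.integers(cfg.n_chrom))]
            length = int(rng.integers(800, 3001))
            start = int(rng.integers(max(1, cfg.chrom_length - length)))
            signal = float(rng.lognormal(np.log(2.0), 0.6))
            plist.append(Peak(GenomicInterval(chrom, start, start + length), signal, sample))
        # planted SE peak clusters on matching-specificity SEDs
        wanted = {"tumor": ("T", "C"), "normal": ("N", "C")}[condition]
        for _, row in sed_truth[sed_truth["specificity"].isin(wanted)].iterrows():
            edges = np.linspace(row["start"], row["end"], 4).astype(int)
            for lo, hi in zip(edges[:-1], edges[1:]):
                if hi <= lo:
                    continue
                signal = float(rng.lognormal(np.log(20.0), 0.3))
                plist.append(Peak(GenomicInterval(row["chrom"], int(lo), int(hi)), signal, sample))
        peaks[sample] = plist
    return sample_sheet, peaks


def _uniform_regions(
    rng: np.random.Generator,
    n: int,
    chroms: Sequence[str],
    chrom_length: int,
    min_len: int,
    max_len: int,
) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(max(1, chrom_length - length)))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def _make_cistrome(
    cfg: SimConfig, rng: np.random.Generator, sed_truth: pd.DataFrame
) -> tuple[dict[str, list[GenomicInterval]], list[str]]:
    """Null TFs are uniform; enriched TFs have tf_density_fold x density in T-SEDs."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    genome_len = cfg.n_chrom * cfg.chrom_length
    tf_names = [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
    enriched = sorted(rng.choice(tf_names, size=cfg.n_enriched_tfs, replace=False).tolist())
    t_seds = sed_truth[sed_truth["specificity"] == "T"]
    t_intervals = list(zip(t_seds["chrom"], t_seds["start"], t_seds["end"]))
    t_total = sum(e - s for _, s, e in t_intervals)

    cistrome: dict[str, list[GenomicInterval]] = {}
    for tf in tf_names:
        n = cfg.tf_regions_per_tf
        if tf in enriched and t_total > 0:
            frac = t_total / genome_len
            n_inside = min(n, int(round(cfg.tf_density_fold * n * frac)))
            regions = _uniform_regions(rng, n - n_inside, chroms, cfg.chrom_length, 100, 1000)
            # extra density inside T-SEDs
            weights = np.asarray([e - s for _, s, e in t_intervals], dtype=float)
            weights /= weights.sum()
            picks = rng.choice(len(t_intervals), size=n_inside, p=weights)
            for pi in picks:
                chrom, s, e = t_intervals[int(pi)]
                length = int(rng.integers(100, 1001))
                start = int(rng.integers(s, max(s + 1, e - length)))
                regions.append(GenomicInterval(chrom, start, start + length))
        else:
            regions = _uniform_regions(rng, n, chroms, cfg.chrom_length, 100, 1000)
        cistrome[tf] = sorted(regions, key=lambda iv: (iv.chrom, iv.start, iv.end))
    return cistrome, enriched


def simulate_null_tf_regions(
    config: SimConfig, n_tfs: int | None = None
) -> dict[str, list[GenomicInterval]]:
    """A cistrome with NO planted enrichment: uniform placement over the genome.

    Region lengths are sampled within [50, 10000] bp so the prepared catalog
    keeps them all.  This is the type-I-error harness for the enrichment
    stage.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    n_tfs = config.n_tfs if n_tfs is None else n_tfs
    out: dict[str, list[GenomicInterval]] = {}
    for i in range(n_tfs):
        regions = _uniform_regions(
            rng, config.tf_regions_per_tf, chroms, config.chrom_length, 50, 10_000
        )
        out[f"NULLTF{i + 1:03d}"] = sorted(regions, key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def planted_lfc(
    cfg: SimConfig, distance: np.ndarray, specificity: np.ndarray
) -> np.ndarray:
    """Pre-noise planted log2FC: effect_lfc * max(0, 1 - d/decay_range), signed.

    Positive toward tumor for genes nearest a T-SED, mirrored negative for
    N-SEDs, zero for common SEDs.
    """
    decay = np.maximum(0.0, 1.0 - distance / cfg.decay_range_bp)
    sign = np.where(specificity == "T", 1.0, np.where(specificity == "N", -1.0, 0.0))
    return cfg.effect_lfc * decay * sign


def _gene_truth(
    cfg: SimConfig,
    genes: Sequence[GeneAnnotation],
    sed_truth: pd.DataFrame,
    core_ids: Sequence[str],
) -> pd.DataFrame:
    from .genomic_core import distance_to_nearest

    targets = [
        (row["chrom"], (row["start"] + row["end"]) // 2, row["sed_id"])
        for _, row in sed_truth.iterrows()
    ]
    if targets:
        nearest = distance_to_nearest([(g.chrom, g.tss) for g in genes], targets)
    else:
        nearest = [(None, None)] * len(genes)
    spec_by_id = dict(zip(sed_truth["sed_id"], sed_truth["specificity"]))
    dist = np.asarray([d if d is not None else np.inf for d, _ in nearest])
    spec = np.asarray([spec_by_id.get(sid, "C") if sid else "C" for _, sid in nearest])
    lfc = planted_lfc(cfg, dist, spec)
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "nearest_sed": [sid for _, sid in nearest],
            "nearest_specificity": spec,
            "distance": dist,
            "planted_lfc": lfc,
            "is_core": [g.gene_id in set(core_ids) for g in genes],
        }
    )


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort with truth tables.

    Reproducible for a fixed seed; each component draws from its own child
    stream of the master seed.
    """
    master = np.random.default_rng(config.seed)
    (
        rng_sed, rng_genes, rng_peaks, rng_cistrome,
        rng_mrna, rng_jq1, rng_erna_noise, rng_erna_counts,
    ) = master.spawn(8)

    genome = GenomeTable(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chrom)}
    )
    sed_truth = _place_seds(config, rng_sed)
    genes, core_ids = _place_genes(config, rng_genes, sed_truth)
    sample_sheet, peaks = _make_peaks(config, rng_peaks, genes, sed_truth)
    cistrome, enriched = _make_cistrome(config, rng_cistrome, sed_truth)
    gene_truth = _gene_truth(config, genes, sed_truth, core_ids)

    # ---- mRNA counts, tumor vs normal -------------------------------------
    n_genes = len(genes)
    base = rng_mrna.lognormal(np.log(config.mean_expression), 1.0, size=n_genes)
    bg_lfc = rng_mrna.normal(0.0, config.background_lfc_sd, size=n_genes)
    true_lfc = gene_truth["planted_lfc"].to_numpy() + bg_lfc
    gene_truth["true_lfc"] = true_lfc

    labels = ["tumor"] * config.n_rna_tumor + ["normal"] * config.n_rna_normal
    lib = rng_mrna.lognormal(0.0, config.library_size_sd, size=len(labels))
    mean_t = base * np.exp2(true_lfc / 2.0)
    mean_n = base * np.exp2(-true_lfc / 2.0)
    means = np.where(
        np.asarray(labels)[None, :] == "tumor", mean_t[:, None], mean_n[:, None]
    ) * lib[None, :]
    counts = _nb_counts(rng_mrna, means, config.nb_dispersion)
    sample_names = [
        f"T{i + 1:02d}" for i in range(config.n_rna_tumor)
    ] + [f"N{i + 1:02d}" for i in range(config.n_rna_normal)]
    mrna_counts = pd.DataFrame(
        counts, index=[g.gene_id for g in genes], columns=sample_names
    )

    # ---- JQ1 vs DMSO cell-line counts -------------------------------------
    is_core = gene_truth["is_core"].to_numpy()
    jq1_counts: dict[str, pd.DataFrame] = {}
    jq1_labels: dict[str, list[str]] = {}
    for li in range(config.n_cell_lines):
        line = f"line{li + 1}"
        bg = rng_jq1.normal(0.0, config.jq1_background_lfc_sd, size=n_genes)
        jq1_lfc = np.where(
            is_core,
            -config.jq1_reversal_fraction * gene_truth["planted_lfc"].to_numpy(),
            bg,
        )
        base_line = rng_jq1.lognormal(np.log(config.mean_expression), 1.0, size=n_genes)
        cols = [f"{line}_JQ1_{r + 1}" for r in range(config.n_cell_reps)] + [
            f"{line}_DMSO_{r + 1}" for r in range(config.n_cell_reps)
        ]
        line_labels = ["JQ1"] * config.n_cell_reps + ["DMSO"] * config.n_cell_reps
        lib = rng_jq1.lognormal(0.0, config.library_size_sd, size=len(cols))
        mean_jq1 = base_line * np.exp2(jq1_lfc / 2.0)
        mean_dmso = base_line * np.exp2(-jq1_lfc / 2.0)
        means = np.where(
            np.asarray(line_labels)[None, :] == "JQ1",
            mean_jq1[:, None],
            mean_dmso[:, None],
        ) * lib[None, :]
        jq1_counts[line] = pd.DataFrame(
            _nb_counts(rng_jq1, means, config.nb_dispersion),
            index=[g.gene_id for g in genes],
            columns=cols,
        )
        jq1_labels[line] = line_labels

    # ---- eRNA counts over planted SED intervals ---------------------------
    n_sed = len(sed_truth)
    spec = sed_truth["specificity"].to_numpy()
    sed_base_effect = np.where(spec == "T", config.effect_lfc, np.where(spec == "N", -config.effect_lfc, 0.0))
    noise = rng_erna_noise.normal(0.0, config.erna_noise_sd, size=n_sed)
    erna_lfc = config.erna_coupling * sed_base_effect + noise
    erna_truth = pd.DataFrame({"sed_id": sed_truth["sed_id"], "true_lfc": erna_lfc})

    base_e = rng_erna_counts.lognormal(np.log(config.erna_mean_expression), 0.8, size=n_sed)
    lib_e = rng_erna_counts.lognormal(0.0, config.library_size_sd, size=len(labels))
    mean_te = base_e * np.exp2(erna_lfc / 2.0)
    mean_ne = base_e * np.exp2(-erna_lfc / 2.0)
    means_e = np.where(
        np.asarray(labels)[None, :] == "tumor", mean_te[:, None], mean_ne[:, None]
    ) * lib_e[None, :]
    erna_counts = pd.DataFrame(
        _nb_counts(rng_erna_counts, means_e, config.nb_dispersion),
        index=sed_truth["sed_id"].tolist(),
        columns=sample_names,
    )

    # ---- gene sets for the pathway stage ----------------------------------
    gene_ids = [g.gene_id for g in genes]
    rng_sets = np.random.default_rng(config.seed + 1_000_003)
    gene_sets: dict[str, set[str]] = {
        "PLANTED_CORE_UP": set(core_ids),
        "PLANTED_TSED_PROXIMAL": set(
            gene_truth.loc[gene_truth["planted_lfc"] > 0.5, "gene_id"]
        ),
    }
    for i in range(8):
        size = int(rng_sets.integers(20, 51))
        gene_sets[f"RANDOM_SET_{i + 1:02d}"] = set(
            rng_sets.choice(gene_ids, size=size, replace=False).tolist()
        )

    truth_sed_intervals = {
        row["sed_id"]: GenomicInterval(row["chrom"], row["start"], row["end"])
        for _, row in sed_truth.iterrows()
    }
    return SyntheticCohort(
        config=config,
        genome=genome,
        genes=genes,
        sample_sheet=sample_sheet,
        peaks=peaks,
        cistrome=cistrome,
        mrna_counts=mrna_counts,
        mrna_labels=labels,
        jq1_counts=jq1_counts,
        jq1_labels=jq1_labels,
        erna_counts=erna_counts,
        erna_labels=labels,
        gene_sets=gene_sets,
        sed_truth=sed_truth,
        gene_truth=gene_truth,
        enriched_tfs=enriched,
        erna_truth=erna_truth,
        truth_sed_intervals=truth_sed_intervals,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort in the flat-file formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = outdir / "genome.chrom.sizes"
    write_chrom_sizes(cohort.genome, p)
    paths["genome"] = p

    p = outdir / "genes.tsv"
    write_gene_table(cohort.genes, p)
    paths["genes"] = p

    with open(outdir / "sample_sheet.tsv", "w") as fh:
        fh.write("sample_id\tcondition\n")
        for sid in sorted(cohort.sample_sheet):
            fh.write(f"{sid}\t{cohort.sample_sheet[sid]}\n")
    paths["sample_sheet"] = outdir / "sample_sheet.tsv"

    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for sid in sorted(cohort.peaks):
        ivs = [
            GenomicInterval(pk.interval.chrom, pk.interval.start, pk.interval.end,
                            name=f"{sid}_peak{i + 1}", score=pk.signal)
            for i, pk in enumerate(cohort.peaks[sid])
        ]
        write_bed(ivs, peak_dir / f"{sid}.bed")
    paths["peaks"] = peak_dir

    with open(outdir / "cistrome.tsv", "w") as fh:
        fh.write("tf\tchrom\tstart\tend\n")
        for tf in sorted(cohort.cistrome):
            for iv in cohort.cistrome[tf]:
                fh.write(f"{tf}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
    paths["cistrome"] = outdir / "cistrome.tsv"

    write_counts(cohort.mrna_counts, outdir / "mrna_counts.tsv")
    paths["mrna_counts"] = outdir / "mrna_counts.tsv"
    for line, counts in sorted(cohort.jq1_counts.items()):
        write_counts(counts, outdir / f"jq1_counts_{line}.tsv")
        paths[f"jq1_counts_{line}"] = outdir / f"jq1_counts_{line}.tsv"
    write_counts(cohort.erna_counts, outdir / "erna_counts.tsv")
    paths["erna_counts"] = outdir / "erna_counts.tsv"

    write_gmt(cohort.gene_sets, outdir / "gene_sets.gmt")
    paths["gene_sets"] = outdir / "gene_sets.gmt"

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    cohort.sed_truth.to_csv(truth_dir / "sed_truth.tsv", sep="\t", index=False)
    cohort.gene_truth.to_csv(truth_dir / "gene_truth.tsv", sep="\t", index=False)
    cohort.erna_truth.to_csv(truth_dir / "erna_truth.tsv", sep="\t", index=False)
    with open(truth_dir / "enriched_tfs.tsv", "w") as fh:
        fh.write("tf\n")
        for tf in cohort.enriched_tfs:
            fh.write(f"{tf}\n")
    paths["truth"] = truth_dir
    return paths
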