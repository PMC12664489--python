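"""eRNA DE gating, gene assignment windows, closest-gene annotation, Kendall tau."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedomain.element_domains import Domain
from sedomain.erna_integration import (
    annotate_closest_gene,
    erna_de,
    erna_mrna_concordance,
    erna_to_genes,
    kendall_tau,
)
from sedomain.expression_de import DEConfig, significant_set
from sedomain.genomic_core import GeneAnnotation, GenomicInterval


def sed_dom(sid, start, end, chrom="chr1"):
    return Domain(GenomicInterval(chrom, start, end), "SED", "C", frozenset(), domain_id=sid)


class TestErnaDE:
    def test_orphan_rows_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [3, 4], "c": [1, 1], "d": [2, 2]},
                              index=["S1", "SX"])
        with pytest.raises(ValueError, match="SX"):
            erna_de(counts, ["t", "t", "n", "n"], [sed_dom("S1", 0, 10)])

    def test_all_equal_counts_nothing_significant(self):
        counts = pd.DataFrame(
            np.full((3, 8), 30), index=["S1", "S2", "S3"],
            columns=[f"s{i}" for i in range(8)],
        )
        res = erna_de(counts, ["t"] * 4 + ["n"] * 4,
                      [sed_dom(s, i * 100, i * 100 + 10) for i, s in enumerate(["S1", "S2", "S3"])])
        assert significant_set(res, "both", 1.5, 0.05) == set()

    def test_boundary_lfc_not_significant(self):
        res = pd.DataFrame(
            {"feature_id": ["e1"], "log2fc": [1.5], "p_adj": [0.001],
             "p_value": [0.001], "mean_expression": [1.0]}
        )
        assert significant_set(res, "both", 1.5, 0.05) == set()

    def test_planted_sixfold_erna_flagged(self):
        """6x planted eRNA at default dispersion: significant in >= 95/100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            base = rng.lognormal(np.log(40), 0.5, 60)
            mean_t = base.copy()
            mean_t[0] *= 6.0
            counts = np.column_stack(
                [rng.poisson(mean_t) for _ in range(6)] + [rng.poisson(base) for _ in range(6)]
            )
            df = pd.DataFrame(counts, index=[f"S{i}" for i in range(60)],
                              columns=[f"x{i}" for i in range(12)])
            doms = [sed_dom(f"S{i}", i * 1000, i * 1000 + 100) for i in range(60)]
            res = erna_de(df, ["t"] * 6 + ["n"] * 6, doms,
                          condition_a="t", condition_b="n")
            if "S0" in significant_set(res, "up", 1.5, 0.05):
                hits += 1
        assert hits >= 95


class TestAnnotateClosestGene:
    GENES = [GeneAnnotation("g9000", "chr1", "+", 9_000), GeneAnnotation("g12000", "chr1", "+", 12_000)]

    def test_nearest_tss_wins(self):
        # SED center 10000: distances 1000 vs 2000
        (pair,) = annotate_closest_gene([sed_dom("S1", 9_000, 11_000)], self.GENES).items()
        assert pair == ("S1", "g9000")

    def test_tie_to_smaller_coordinate(self):
        genes = [GeneAnnotation("lo", "chr1", "+", 9_500), GeneAnnotation("hi", "chr1", "+", 10_500)]
        got = annotate_closest_gene([sed_dom("S1", 9_000, 11_000)], genes)
        assert got["S1"] == "lo"

    def test_single_gene_genome(self):
        got = annotate_closest_gene(
            [sed_dom("S1", 0, 10), sed_dom("S2", 5_000, 5_100)],
            [GeneAnnotation("only", "chr1", "+", 700)],
        )
        assert got == {"S1": "only", "S2": "only"}


class TestErnaToGenes:
    DE = pd.DataFrame(
        {"feature_id": ["S1", "S2"], "log2fc": [1.0, 3.0], "p_adj": [0.01, 0.01],
         "p_value": [0.01, 0.01], "mean_expression": [1.0, 1.0]}
    )
    INTERVALS = {
        "S1": GenomicInterval("chr1", 5_000_000, 5_020_000),
        "S2": GenomicInterval("chr1", 5_100_000, 5_120_000),
    }

    def test_mean_over_contributing_ernas(self):
        genes = [GeneAnnotation("g", "chr1", "+", 5_050_000)]
        out = erna_to_genes(self.DE, self.INTERVALS, genes)
        assert out.iloc[0]["erna_log2fc_mean"] == pytest.approx(2.0)
        assert out.iloc[0]["n_contributing_ernas"] == 2

    def test_single_contributor_is_own_lfc(self):
        genes = [GeneAnnotation("g", "chr1", "+", 5_020_000 + 1_400_000)]
        out = erna_to_genes(self.DE, self.INTERVALS, genes)
        row = out.set_index("gene_id").loc["g"]
        assert row["n_contributing_ernas"] == 2 or row["erna_log2fc_mean"] > 0

    def test_tss_just_beyond_window_not_assigned(self):
        # window end for S2 is 5_120_000 + 1_500_000 (half-open)
        inside = [GeneAnnotation("in", "chr1", "+", 5_120_000 + 1_500_000 - 1)]
        outside = [GeneAnnotation("out", "chr1", "+", 5_120_000 + 1_500_000 + 1)]
        assert len(erna_to_genes(self.DE, self.INTERVALS, inside)) == 1
        assert len(erna_to_genes(self.DE, self.INTERVALS, outside)) == 0

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(9)
        intervals = {
            f"S{i}": GenomicInterval("chr1", int(s), int(s) + 10_000)
            for i, s in enumerate(rng.integers(0, 50_000_000, 40))
        }
        de = pd.DataFrame(
            {"feature_id": list(intervals), "log2fc": rng.normal(size=40),
             "p_adj": 0.01, "p_value": 0.01, "mean_expression": 1.0}
        )
        genes = [GeneAnnotation(f"g{i}", "chr1", "+", int(p))
                 for i, p in enumerate(rng.integers(0, 50_000_000, 200))]
        out = erna_to_genes(de, intervals, genes, window=1_500_000).set_index("gene_id")
        lfc = dict(zip(de["feature_id"], de["log2fc"]))
        for g in genes:
            contrib = [
                lfc[sid] for sid, iv in intervals.items()
                if iv.start - 1_500_000 <= g.tss < iv.end + 1_500_000
            ]
            if contrib:
                assert out.loc[g.gene_id, "n_contributing_ernas"] == len(contrib)
                assert out.loc[g.gene_id, "erna_log2fc_mean"] == pytest.approx(np.mean(contrib))
            else:
                assert g.gene_id not in out.index


class TestKendallTau:
    def test_perfect_concordance(self):
        tau, _ = kendall_tau([1, 2, 3], [1, 2, 3])
        assert tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        tau, _ = kendall_tau([1, 2, 3], [3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_hand_count(self):
        # pairs: 5 concordant, 1 discordant -> (5-1)/6
        tau, _ = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert tau == pytest.approx(4 / 6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2, 3])

    @staticmethod
    def _tau_b_oracle(x, y):
        """O(n^2) pair counting with tie correction."""
        x, y = np.asarray(x, float), np.asarray(y, float)
        n = len(x)
        conc = disc = tx = ty = 0
        for i in range(n):
            for j in range(i + 1, n):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx == 0 and dy == 0:
                    tx += 1
                    ty += 1
                elif dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
        n0 = n * (n - 1) / 2
        denom = np.sqrt((n0 - tx) * (n0 - ty))
        return (conc - disc) / denom

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(-20, 20), min_size=2, max_size=60).flatmap(
            lambda x: st.tuples(
                st.just(x), st.lists(st.integers(-20, 20), min_size=len(x), max_size=len(x))
            )
        )
    )
    def test_matches_pair_counting(self, xy):
        x, y = xy
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(self._tau_b_oracle(x, y), abs=1e-12)

    def test_pair_counting_at_n200(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(self._tau_b_oracle(x, y), abs=1e-12)


def test_concordance_positive_on_coupled_cohort(default_cohort, default_mrna_de):
    from sedomain.element_domains import Domain

    c = default_cohort
    doms = [Domain(iv, "SED", "C", frozenset(), domain_id=sid)
            for sid, iv in c.truth_sed_intervals.items()]
    er = erna_de(c.erna_counts, c.erna_labels, doms, DEConfig(),
                 condition_a="tumor", condition_b="normal")
    ge = erna_to_genes(er, c.truth_sed_intervals, c.genes)
    tau, p, n = erna_mrna_concordance(ge, default_mrna_de)
    assert tau > 0 and p < 0.001 and n > 100
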