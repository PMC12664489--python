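"""Promoter/enhancer classification, ROSE thresholding, and domain pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedomain.element_domains import (
    ElementConfig,
    Peak,
    RegulatoryElement,
    call_elements,
    classify_peaks,
    pool_domains,
    rose_cutoff,
    score_enhancers,
)
from sedomain.genomic_core import GeneAnnotation, GenomicInterval


def peak(start, end, signal=1.0, sample="s1", chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), signal, sample)


GENE = GeneAnnotation("G1", "chr1", "+", 100_000)


class TestClassifyPeaks:
    def test_peak_in_tss_window_is_promoter(self):
        (el,) = classify_peaks([peak(98_000, 99_000)], [GENE])
        assert el.element_class == "promoter"

    def test_peak_ending_at_window_edge_is_enhancer(self):
        # window [97500, 102500]; half-open peak up to 97000 does not reach it
        (el,) = classify_peaks([peak(90_000, 97_000)], [GENE])
        assert el.element_class == "enhancer"

    def test_two_gene_windows_assign_once(self):
        genes = [GENE, GeneAnnotation("G2", "chr1", "-", 101_000)]
        els = classify_peaks([peak(98_000, 103_000)], genes)
        assert [e.element_class for e in els] == ["promoter"]

    def test_partition_exhaustive_exclusive(self):
        peaks = [peak(s, s + 500) for s in range(0, 200_000, 7_000)]
        els = classify_peaks(peaks, [GENE])
        assert len(els) == len(peaks)
        assert all(e.element_class in ("promoter", "enhancer") for e in els)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            classify_peaks([peak(0, 10)], [])


class TestScoreEnhancers:
    def enh(self, start, end, sample="s1"):
        return RegulatoryElement(GenomicInterval("chr1", start, end), "enhancer", sample, 0.0)

    def test_single_full_cover_peak(self):
        (el,) = score_enhancers([self.enh(0, 1000)], [peak(0, 1000, 2.0)])
        assert el.se_score == pytest.approx(2000.0)

    def test_zero_signal_gives_zero(self):
        (el,) = score_enhancers([self.enh(0, 1000)], [peak(0, 1000, 0.0)])
        assert el.se_score == 0.0

    def test_two_partial_peaks_hand_sum(self):
        # signal 1.0 over 500 bp + signal 3.0 over 100 bp = 800
        (el,) = score_enhancers(
            [self.enh(0, 1000)], [peak(0, 500, 1.0), peak(600, 700, 3.0)]
        )
        assert el.se_score == pytest.approx(800.0)

    def test_overlap_clipped_to_element(self):
        (el,) = score_enhancers([self.enh(100, 200)], [peak(0, 1000, 2.0)])
        assert el.se_score == pytest.approx(200.0)


class TestRoseCutoff:
    @staticmethod
    def _oracle(scores):
        """Brute-force argmax over all indices of the scaled rank-score gap."""
        s = sorted(scores)
        n = len(s)
        if s[-1] == s[0]:
            return s[-1]
        best_i, best_v = 0, -np.inf
        for i in range(n):
            x = i / (n - 1)
            y = (s[i] - s[0]) / (s[-1] - s[0])
            if x - y >= best_v:  # >= keeps the largest index on ties
                best_i, best_v = i, x - y
        return s[best_i]

    def test_quadratic_curve_cuts_at_half(self):
        n = 1000
        scores = [(i / n) ** 2 for i in range(1, n + 1)]
        cut = rose_cutoff(scores)
        rank = sorted(scores).index(cut)
        assert abs(rank / (n - 1) - 0.5) <= 1.5 / n

    def test_constant_scores_yield_no_superenhancers(self):
        cut = rose_cutoff([5.0] * 10)
        assert sum(s > cut for s in [5.0] * 10) == 0

    def test_linear_scores_tie_to_last_index(self):
        scores = list(range(1, 51))
        cut = rose_cutoff(scores)
        assert cut == 50
        assert sum(s > cut for s in scores) == 0

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            rose_cutoff([1.0, 2.0])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=3, max_size=200))
    def test_matches_bruteforce_argmax(self, scores):
        assert rose_cutoff(scores) == self._oracle(scores)

    def test_convex_random_curves_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(10, 400))
            scores = np.sort(rng.lognormal(0, rng.uniform(0.3, 2.0), size=n))
            assert rose_cutoff(scores) == self._oracle(scores.tolist())

    def test_se_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        scores = rng.lognormal(0, 1, 200)
        cuts = np.linspace(scores.min(), scores.max(), 20)
        counts = [(scores > c).sum() for c in cuts]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCallElements:
    def test_superenhancers_require_score_above_cutoff(self):
        genes = [GeneAnnotation("G1", "chr1", "+", 1_000_000)]
        peaks = [peak(s, s + 1000, signal=1.0) for s in range(0, 50_000, 2_000)]
        peaks += [peak(200_000, 230_000, signal=50.0)]
        els = call_elements(peaks, genes)
        ses = [e for e in els if e.element_class == "super_enhancer"]
        assert len(ses) == 1 and ses[0].interval.start == 200_000

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError):
            call_elements([peak(0, 10, sample="a"), peak(20, 30, sample="b")], [GENE])


class TestPoolDomains:
    def se(self, start, end, sample):
        return RegulatoryElement(
            GenomicInterval("chr1", start, end), "super_enhancer", sample, 1.0
        )

    CONDITIONS = {"tumor1": "tumor", "tumor2": "tumor", "normal1": "normal"}

    def test_cross_condition_overlap_is_common(self):
        doms = pool_domains(
            {"tumor1": [self.se(0, 1000, "tumor1")], "normal1": [self.se(500, 1500, "normal1")]},
            "SE",
            self.CONDITIONS,
        )
        (d,) = doms
        assert (d.interval.start, d.interval.end) == (0, 1500)
        assert d.specificity == "C"
        assert d.supporting_samples == frozenset({"tumor1", "normal1"})

    def test_tumor_only_is_tumor_specific(self):
        (d,) = pool_domains(
            {"tumor1": [self.se(0, 1000, "tumor1")], "normal1": []},
            "SE",
            self.CONDITIONS,
        )
        assert d.specificity == "T"

    def test_all_samples_is_common(self):
        (d,) = pool_domains(
            {
                "tumor1": [self.se(0, 1000, "tumor1")],
                "tumor2": [self.se(100, 900, "tumor2")],
                "normal1": [self.se(0, 500, "normal1")],
            },
            "SE",
            self.CONDITIONS,
        )
        assert d.specificity == "C" and len(d.supporting_samples) == 3

    def test_order_independent(self):
        sets = {
            "tumor1": [self.se(0, 1000, "tumor1"), self.se(5000, 6000, "tumor1")],
            "normal1": [self.se(500, 1500, "normal1")],
        }
        fwd = pool_domains(sets, "SE", self.CONDITIONS)
        rev = pool_domains(dict(reversed(list(sets.items()))), "SE", self.CONDITIONS)
        assert [(d.interval, d.specificity, d.supporting_samples) for d in fwd] == [
            (d.interval, d.specificity, d.supporting_samples) for d in rev
        ]

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            pool_domains({"tumor1": []}, "X", self.CONDITIONS)

    def test_domains_pairwise_nonoverlapping(self, default_sed_domains):
        by_chrom = {}
        for d in default_sed_domains:
            by_chrom.setdefault(d.interval.chrom, []).append(d.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda x: x.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))


def test_planted_superenhancers_recovered_in_matching_domains(
    default_cohort, default_sed_domains
):
    """>= 95% of planted SEs land inside a recovered SED of matching specificity."""
    by_spec = {}
    for d in default_sed_domains:
        by_spec.setdefault(d.specificity, []).append(d.interval)
    ok = 0
    for _, row in default_cohort.sed_truth.iterrows():
        for iv in by_spec.get(row["specificity"], []):
            if iv.chrom == row["chrom"] and iv.start <= row["start"] and iv.end >= row["end"]:
                ok += 1
                break
    assert ok / len(default_cohort.sed_truth) >= 0.95
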