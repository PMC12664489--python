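"""Shade construction, overlap counting, exact Fisher test, worst-case selection."""

from fractions import Fraction
from math import factorial, isclose, log

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedomain.element_domains import Domain
from sedomain.genomic_core import GenomeTable, GenomicInterval
from sedomain.tf_enrichment import (
    TFEnrichmentRecord,
    delta_enrichment,
    enrich_tfs,
    fisher_exact_2x2,
    make_shades,
    overlap_table,
    prepare_cistrome,
)

GENOME = GenomeTable({"chr1": 10_000_000})


def dom(start, end, spec="T", chrom="chr1", did=None):
    return Domain(
        GenomicInterval(chrom, start, end), "SED", spec, frozenset({"s"}), domain_id=did
    )


def hypergeom_p_oracle(a, b, c, d):
    """Two-sided Fisher p by exact rational enumeration (independent of the
    implementation's integer-numerator shortcut)."""

    def pmf(x, m1, m2, k):
        def C(n, r):
            if r < 0 or r > n:
                return 0
            return factorial(n) // (factorial(r) * factorial(n - r))

        return Fraction(C(m1, x) * C(m2, k - x), C(m1 + m2, k))

    m1, m2, k = a + b, c + d, a + c
    p_obs = pmf(a, m1, m2, k)
    total = Fraction(0)
    for x in range(max(0, k - m2), min(k, m1) + 1):
        px = pmf(x, m1, m2, k)
        if px <= p_obs:
            total += px
    return float(total)


class TestFisherExact:
    def test_symmetric_table(self):
        orr, p = fisher_exact_2x2(5, 5, 5, 5)
        assert orr == 1.0 and p == 1.0

    def test_strong_diagonal_table_matches_enumeration(self):
        orr, p = fisher_exact_2x2(9, 1, 1, 9)
        assert orr == 81.0
        assert p == pytest.approx(hypergeom_p_oracle(9, 1, 1, 9), abs=1e-12)

    def test_zero_cell_haldane_or_but_exact_p(self):
        orr, p = fisher_exact_2x2(0, 10, 5, 5)
        assert orr == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))
        assert p == pytest.approx(hypergeom_p_oracle(0, 10, 5, 5), abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 3, 4)

    def test_matches_enumeration_over_margin_grid(self):
        # every table with both margins <= 12 (exhaustive at small scale)
        for m1 in range(1, 13):
            for m2 in range(1, 13):
                for a in range(m1 + 1):
                    for c in range(m2 + 1):
                        if a + c == 0 or (m1 - a) + (m2 - c) == 0:
                            continue
                        _, p = fisher_exact_2x2(a, m1 - a, c, m2 - c)
                        assert isclose(
                            p, hypergeom_p_oracle(a, m1 - a, c, m2 - c),
                            rel_tol=0, abs_tol=1e-10,
                        )

    def test_agrees_with_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, size=4)
            if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
                continue
            _, p = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(fisher_exact([[a, b], [c, d]])[1], rel=1e-6)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 25), st.integers(1, 25), st.integers(1, 25), st.integers(0, 25))
    def test_swap_inverts_or_keeps_p(self, a, b, c, d):
        # swapping test and control rows inverts the OR and keeps p
        if a + c == 0 or b + d == 0:
            return
        or1, p1 = fisher_exact_2x2(a, b, c, d)
        or2, p2 = fisher_exact_2x2(c, d, a, b)
        assert p1 == pytest.approx(p2, abs=1e-12)
        if 0 not in (a, b, c, d):
            assert or1 == pytest.approx(1.0 / or2)


class TestPrepareCistrome:
    def test_merge_then_keep(self):
        raw = {"TF1": [GenomicInterval("chr1", 0, 30), GenomicInterval("chr1", 40, 60)]}
        out = prepare_cistrome(raw, merge_distance=10_000)
        assert [(iv.start, iv.end) for iv in out["TF1"]] == [(0, 60)]

    def test_short_region_dropped(self):
        raw = {"TF1": [GenomicInterval("chr1", 0, 40)]}
        assert prepare_cistrome(raw, 0) == {}

    def test_overlong_merged_region_dropped_eliminating_tf(self):
        raw = {"TF1": [GenomicInterval("chr1", 0, 6000), GenomicInterval("chr1", 6000, 12_000)]}
        assert prepare_cistrome(raw, 0) == {}


class TestMakeShades:
    def test_shade_formula(self):
        ss = make_shades([dom(50_000, 52_000)], 10_000, GENOME)
        assert [(iv.start, iv.end) for iv in ss.intervals] == [
            (38_000, 40_000),
            (62_000, 64_000),
        ]

    def test_out_of_bounds_shade_dropped_whole(self):
        ss = make_shades([dom(5_000, 7_000)], 10_000, GENOME)
        assert [(iv.start, iv.end) for iv in ss.intervals] == [(17_000, 19_000)]
        assert ss.n_dropped == 1

    def test_adjacent_domains_shades_merge(self):
        # downstream shade of A is [12000,14000); upstream shade of B [11000,13000)
        ss = make_shades([dom(0, 2_000), dom(23_000, 25_000)], 10_000, GENOME)
        merged = [(iv.start, iv.end) for iv in ss.intervals]
        assert (11_000, 14_000) in merged

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            make_shades([dom(0, 100)], 0, GENOME)

    def test_premerge_length_bounded_by_twice_domain_length(self):
        rng = np.random.default_rng(5)
        doms = [
            dom(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 9_000_000, 50), rng.integers(1000, 50_000, 50))
        ]
        ss = make_shades(doms, 10_000, GENOME, merge=False)
        assert sum(iv.length for iv in ss.intervals) <= 2 * sum(
            d.interval.length for d in doms
        )
        # nothing clipped here means exact equality
        if ss.n_dropped == 0:
            assert sum(iv.length for iv in ss.intervals) == 2 * sum(
                d.interval.length for d in doms
            )


class TestOverlapTable:
    TF = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 5_000, 5_100)]

    def test_counts(self):
        test = [GenomicInterval("chr1", 150, 160), GenomicInterval("chr1", 5_050, 5_060),
                GenomicInterval("chr1", 9_000, 9_100)]
        control = [GenomicInterval("chr1", 100, 110), GenomicInterval("chr1", 8_000, 8_100)]
        assert overlap_table(test, control, self.TF) == (2, 1, 1, 1)

    def test_region_counted_once_despite_two_hits(self):
        test = [GenomicInterval("chr1", 0, 6_000)]
        control = [GenomicInterval("chr1", 9_000, 9_100)]
        assert overlap_table(test, control, self.TF) == (1, 0, 0, 1)

    def test_empty_tf_catalog_gives_zero_overlaps(self):
        test = [GenomicInterval("chr1", 0, 10)]
        control = [GenomicInterval("chr1", 20, 30)]
        assert overlap_table(test, control, []) == (0, 1, 0, 1)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_table([], [GenomicInterval("chr1", 0, 10)], self.TF)


class TestWorstCaseSelection:
    def test_selected_is_min_or_max_p(self):
        doms_t = [dom(s, s + 2_000, did=f"d{i}") for i, s in enumerate(range(100_000, 500_000, 40_000))]
        cistrome = {"TF1": [GenomicInterval("chr1", s + 500, s + 700) for s in range(100_000, 300_000, 40_000)]}
        recs = enrich_tfs(doms_t, cistrome, GENOME, D_values=(10_000, 100_000))
        (r,) = recs
        assert r.selected_or == min(v[0] for v in r.per_D.values())
        assert r.selected_p == max(v[1] for v in r.per_D.values())

    def test_single_tf_bonferroni_is_raw(self):
        doms_t = [dom(s, s + 2_000, did=f"d{i}") for i, s in enumerate(range(100_000, 500_000, 40_000))]
        cistrome = {"TF1": [GenomicInterval("chr1", 100_500, 100_700)]}
        (r,) = enrich_tfs(doms_t, cistrome, GENOME)
        assert r.p_bonferroni == pytest.approx(min(1.0, r.selected_p))

    def test_componentwise_selection_documented_pairing(self):
        rec = TFEnrichmentRecord(
            "t", {10_000: (2.0, 0.01, (1, 1, 1, 1)), 100_000: (1.5, 0.05, (1, 1, 1, 1))},
            1.5, 0.05, 0.05, True,
        )
        assert (rec.selected_or, rec.selected_p) == (1.5, 0.05)


class TestDelta:
    def rec(self, orr):
        return TFEnrichmentRecord("TF1", {}, orr, 0.5, 0.5, False)

    def test_equal_ors_zero_delta(self):
        assert delta_enrichment(self.rec(2.0), self.rec(2.0)) == 0.0

    def test_closed_form(self):
        assert delta_enrichment(self.rec(np.e ** 2), self.rec(np.e)) == pytest.approx(1.0)

    def test_mismatched_tf_rejected(self):
        other = TFEnrichmentRecord("TF2", {}, 1.0, 0.5, 0.5, False)
        with pytest.raises(ValueError):
            delta_enrichment(self.rec(1.0), other)
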