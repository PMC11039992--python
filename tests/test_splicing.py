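"""Unit tests for annotation merging, event filtering/classification,
hypergeometric enrichment, and the IR summary."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from minorsplice.errors import ConsistencyError, FormatError, InvalidArgumentError
from minorsplice.splicing import (
    ASEvent,
    EventClass,
    IntronAnnotation,
    IRRecord,
    classify_event,
    classify_events,
    differential_ir,
    enrichment_test,
    filter_significant_events,
    merge_u12_annotations,
)
from minorsplice.splicing.enrichment import benjamini_hochberg


def intron(chrom, start, end, strand="+", subtype=None, source="db"):
    return IntronAnnotation(
        chrom=chrom, start=start, end=end, strand=strand,
        subtype=subtype, sources=frozenset({source}),
    )


def event(gene_id="gA", etype="AA", start=310, end=330, strand="+",
          psi_a=0.5, psi_b=0.7, pr=0.99, chrom="chr1"):
    return ASEvent(
        gene_id=gene_id, event_type=etype, chrom=chrom, start=start, end=end,
        strand=strand, psi_a=psi_a, psi_b=psi_b, probability=pr,
    )


# -- exact hypergeometric oracle ---------------------------------------

def hypergeom_pmf_exact(x, N, K, n):
    """P[X = x] by direct combinatorial enumeration."""
    if x < max(0, n - (N - K)) or x > min(n, K):
        return 0.0
    return math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)


def upper_tail_exact(k, N, K, n):
    return sum(hypergeom_pmf_exact(x, N, K, n) for x in range(k, min(n, K) + 1))


def lower_tail_exact(k, N, K, n):
    return sum(hypergeom_pmf_exact(x, N, K, n) for x in range(0, k + 1))


class TestMergeAnnotations:
    def test_duplicate_collapsed_sources_union(self):
        a = intron("chr1", 100, 200, source="db1")
        b = intron("chr1", 100, 200, source="db2")
        merged = merge_u12_annotations([[a], [b]])
        assert len(merged) == 1
        assert merged[0].sources == {"db1", "db2"}

    def test_one_bp_difference_not_merged(self):
        a = intron("chr1", 100, 200)
        b = intron("chr1", 100, 201)
        assert len(merge_u12_annotations([[a], [b]])) == 2

    def test_strand_distinguishes(self):
        a = intron("chr1", 100, 200, strand="+")
        b = intron("chr1", 100, 200, strand="-")
        assert len(merge_u12_annotations([[a], [b]])) == 2

    def test_three_list_union_oracle(self):
        # 4/5/6 records, 3 shared across all lists: union = 4+5+6-2*3 = 9
        l1 = [intron("chr1", s, s + 100, source="l1") for s in (10, 300, 600, 1000)]
        l2 = [intron("chr1", s, s + 100, source="l2") for s in (10, 300, 600, 2000, 2200)]
        l3 = [intron("chr1", s, s + 100, source="l3") for s in (10, 300, 600, 3000, 3200, 3400)]
        keys = {(r.chrom, r.start, r.end, r.strand) for recs in (l1, l2, l3) for r in recs}
        merged = merge_u12_annotations([l1, l2, l3])
        assert len(merged) == len(keys) == 9
        shared_rec = [r for r in merged if r.start == 10][0]
        assert shared_rec.sources == {"l1", "l2", "l3"}

    def test_idempotent(self):
        lists = [
            [intron("chr1", 10, 50, source="a"), intron("chr2", 5, 99, source="a")],
            [intron("chr1", 10, 50, source="b")],
        ]
        once = merge_u12_annotations(lists)
        twice = merge_u12_annotations([once, once])
        assert twice == once

    def test_sorted_output(self):
        merged = merge_u12_annotations(
            [[intron("chr2", 5, 10), intron("chr1", 50, 90), intron("chr1", 5, 10)]]
        )
        assert [(r.chrom, r.start) for r in merged] == [("chr1", 5), ("chr1", 50), ("chr2", 5)]

    def test_malformed_interval_rejected(self):
        with pytest.raises(FormatError):
            intron("chr1", 200, 100)

    def test_subtype_conflict_dropped(self):
        a = intron("chr1", 1, 9, subtype="GT-AG", source="a")
        b = intron("chr1", 1, 9, subtype="AT-AC", source="b")
        merged = merge_u12_annotations([[a], [b]])
        assert merged[0].subtype is None


class TestFilterSignificantEvents:
    def test_retained_above_both_thresholds(self):
        ev = event(psi_a=0.5, psi_b=0.4, pr=0.95)  # dPsi = -0.10
        assert filter_significant_events([ev]) == [ev]

    def test_pr_exactly_at_threshold_excluded(self):
        ev = event(psi_a=0.2, psi_b=0.7, pr=0.9)
        assert filter_significant_events([ev]) == []

    def test_dpsi_exactly_at_threshold_excluded(self):
        ev = event(psi_a=0.50, psi_b=0.55, pr=0.99)  # |dPsi| = 0.05
        assert filter_significant_events([ev]) == []

    def test_hand_filtered_fixture(self):
        rows = [
            # (psi_a, psi_b, pr, kept?)
            (0.5, 0.7, 0.95, True),
            (0.5, 0.7, 0.90, False),   # pr at boundary
            (0.5, 0.55, 0.95, False),  # dPsi at boundary
            (0.5, 0.56, 0.95, True),
            (0.5, 0.30, 0.91, True),
            (0.5, 0.50, 0.99, False),  # dPsi = 0
            (0.9, 0.99, 0.89, False),  # pr below
            (0.1, 0.30, 0.91, True),
            (0.5, 0.44, 0.95, True),
            (0.5, 0.46, 0.99, False),  # |dPsi| = 0.04
        ]
        events = [event(psi_a=a, psi_b=b, pr=p) for a, b, p, _ in rows]
        kept = filter_significant_events(events)
        assert kept == [ev for ev, (_, _, _, keep) in zip(events, rows) if keep]

    def test_order_preserved(self):
        events = [event(pr=0.95, psi_b=0.7), event(pr=0.96, psi_b=0.8)]
        assert filter_significant_events(events) == events

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        events = [
            event(psi_a=0.5, psi_b=float(rng.uniform(0, 1)), pr=float(rng.uniform(0, 1)))
            for _ in range(100)
        ]
        counts = []
        for pr_min in (0.0, 0.5, 0.9, 0.99):
            counts.append(len(filter_significant_events(events, pr_min=pr_min)))
        assert counts == sorted(counts, reverse=True)
        counts = []
        for dpsi_min in (0.0, 0.05, 0.2, 0.5):
            counts.append(len(filter_significant_events(events, dpsi_min=dpsi_min)))
        assert counts == sorted(counts, reverse=True)


class TestClassifyEvent:
    # toy_gene: exons 0-100,200-300,400-500,600-700,800-900 (+ strand)
    # U12 intron = 300-400; flanking = exons 200-300/400-500 and
    # introns 100-200/500-600.

    def test_within_u12(self, toy_u12, toy_gene_models):
        ev = event(start=350, end=370)
        assert classify_event(ev, toy_u12, toy_gene_models) is EventClass.WITHIN_U12

    def test_acceptor_inside_u12(self, toy_u12, toy_gene_models):
        ev = event(start=390, end=420)  # overlaps intron 3' end
        assert classify_event(ev, toy_u12, toy_gene_models) is EventClass.WITHIN_U12

    def test_downstream_exon_proximal(self, toy_u12, toy_gene_models):
        ev = event(start=410, end=450)
        assert classify_event(ev, toy_u12, toy_gene_models) is EventClass.PROXIMAL_U12

    def test_upstream_exon_proximal(self, toy_u12, toy_gene_models):
        ev = event(start=250, end=280)
        assert classify_event(ev, toy_u12, toy_gene_models) is EventClass.PROXIMAL_U12

    def test_adjacent_intron_proximal(self, toy_u12, toy_gene_models):
        ev = event(start=150, end=170)  # intron0, one intron upstream
        assert classify_event(ev, toy_u12, toy_gene_models) is EventClass.PROXIMAL_U12

    def test_distal_in_u12_gene(self, toy_u12, toy_gene_models):
        ev = event(start=10, end=40)  # first exon, two features away
        assert classify_event(ev, toy_u12, toy_gene_models) is EventClass.U12_GENE_DISTAL

    def test_u2_only_background(self, toy_u12, toy_gene_models):
        ev = event(gene_id="gB", start=10_050, end=10_080)
        assert (
            classify_event(ev, toy_u12, toy_gene_models)
            is EventClass.U2_ONLY_BACKGROUND
        )

    def test_strand_mismatch_not_within(self, toy_gene_models):
        minus = [intron("chr1", 300, 400, strand="-")]
        ev = event(start=350, end=370, strand="+")
        # minus-strand U12 intron is not "within" for a plus-strand event,
        # and it is outside gA's annotation set entirely (strand differs)
        assert classify_event(ev, minus, toy_gene_models) is EventClass.U2_ONLY_BACKGROUND

    def test_unknown_gene_raises(self, toy_u12, toy_gene_models):
        ev = event(gene_id="missing")
        with pytest.raises(ConsistencyError):
            classify_event(ev, toy_u12, toy_gene_models)

    def test_skip_list_collects_unknown_genes(self, toy_u12, toy_gene_models):
        good = event(start=350, end=370)
        bad = event(gene_id="missing")
        classified, skipped = classify_events([good, bad], toy_u12, toy_gene_models)
        assert len(classified) == 1 and skipped == [bad]

    def test_twelve_event_manual_oracle(self, toy_u12, toy_gene_models):
        # manual overlap/adjacency evaluation of 12 positions in gA/gB
        cases = [
            ((300, 400), EventClass.WITHIN_U12),    # exactly the intron
            ((395, 405), EventClass.WITHIN_U12),    # straddles 3'ss
            ((295, 305), EventClass.WITHIN_U12),    # straddles 5'ss
            ((350, 351), EventClass.WITHIN_U12),    # inside
            ((200, 300), EventClass.PROXIMAL_U12),  # upstream exon
            ((400, 500), EventClass.PROXIMAL_U12),  # downstream exon
            ((100, 200), EventClass.PROXIMAL_U12),  # upstream intron
            ((500, 600), EventClass.PROXIMAL_U12),  # downstream intron
            ((620, 660), EventClass.U12_GENE_DISTAL),  # exon 2 past flank
            ((0, 50), EventClass.U12_GENE_DISTAL),
            ((850, 880), EventClass.U12_GENE_DISTAL),
            ((700, 780), EventClass.U12_GENE_DISTAL),  # intron3, 2 past
        ]
        for (s, e), expected in cases:
            assert classify_event(event(start=s, end=e), toy_u12, toy_gene_models) is expected, (s, e)

    def test_partition_property(self, toy_u12, toy_gene_models):
        rng = np.random.default_rng(0)
        events = []
        for _ in range(200):
            gid = "gA" if rng.random() < 0.7 else "gB"
            lo = 0 if gid == "gA" else 10_000
            hi = 900 if gid == "gA" else 10_500
            s = int(rng.integers(lo, hi - 10))
            events.append(event(gene_id=gid, start=s, end=s + 10))
        classified, skipped = classify_events(events, toy_u12, toy_gene_models)
        assert len(classified) + len(skipped) == len(events)
        counts = {cls: 0 for cls in EventClass}
        for _, cls in classified:
            counts[cls] += 1
        assert sum(counts.values()) == len(classified)


class TestEnrichmentTest:
    def _classified(self, u12_types, bg_types):
        out = []
        for i, t in enumerate(u12_types):
            out.append((event(etype=t, start=10 + i, end=30 + i), EventClass.WITHIN_U12))
        for i, t in enumerate(bg_types):
            out.append((event(etype=t, start=10 + i, end=30 + i), EventClass.U2_ONLY_BACKGROUND))
        return out

    def test_worked_example(self):
        # k=5, n=10, K=10, N=110 -> fold vs background = (5/10)/(5/100) = 10
        classified = self._classified(
            ["AA"] * 5 + ["CE"] * 5, ["AA"] * 5 + ["CE"] * 95
        )
        res = enrichment_test(classified, "AA")
        assert (res.k, res.n, res.K, res.N) == (5, 10, 10, 110)
        assert res.fold == pytest.approx(10.0)
        assert res.fold_overall == pytest.approx((5 / 10) / (10 / 110))
        assert res.p_upper == pytest.approx(upper_tail_exact(5, 110, 10, 10), rel=1e-12)
        assert res.p_lower == pytest.approx(lower_tail_exact(5, 110, 10, 10), rel=1e-12)

    def test_identical_composition_null(self):
        classified = self._classified(["AA", "CE", "CE", "CE"], ["AA", "CE", "CE", "CE"] * 5)
        res = enrichment_test(classified, "AA")
        assert res.fold == pytest.approx(1.0)
        assert res.p_upper >= 0.5

    def test_depletion_boundary(self):
        classified = self._classified(["CE"] * 10, ["AA"] * 5 + ["CE"] * 45)
        res = enrichment_test(classified, "AA")
        assert res.fold == 0.0
        assert res.p_lower == pytest.approx(lower_tail_exact(0, 60, 5, 10), rel=1e-12)

    def test_exact_enumeration_small_tables(self):
        # spot sweep (full N <= 12 sweep lives in the acceptance suite)
        for N in range(2, 10):
            for n in range(1, N):
                for K in range(0, N + 1):
                    for k in range(max(0, n - (N - K)), min(n, K) + 1):
                        assert hypergeom.sf(k - 1, N, K, n) == pytest.approx(
                            upper_tail_exact(k, N, K, n), abs=1e-12
                        )

    def test_survival_identity_large(self):
        # P[X >= k] = 1 - P[X <= k-1] to 1e-12 at large N
        N, K, n, k = 5000, 400, 300, 40
        assert hypergeom.sf(k - 1, N, K, n) == pytest.approx(
            1.0 - hypergeom.cdf(k - 1, N, K, n), abs=1e-12
        )

    def test_proximal_counts_in_u12_stratum(self):
        classified = [
            (event(etype="AA"), EventClass.PROXIMAL_U12),
            (event(etype="CE"), EventClass.WITHIN_U12),
            (event(etype="AA"), EventClass.U2_ONLY_BACKGROUND),
            (event(etype="CE"), EventClass.U2_ONLY_BACKGROUND),
        ]
        res = enrichment_test(classified, "AA")
        assert (res.k, res.n) == (1, 2)

    def test_distal_excluded_from_both_strata(self):
        classified = [
            (event(etype="AA"), EventClass.WITHIN_U12),
            (event(etype="AA"), EventClass.U12_GENE_DISTAL),
            (event(etype="CE"), EventClass.U2_ONLY_BACKGROUND),
        ]
        res = enrichment_test(classified, "AA")
        assert res.N == 2 and res.K == 1

    def test_empty_stratum_rejected(self):
        classified = [(event(etype="AA"), EventClass.WITHIN_U12)]
        with pytest.raises(InvalidArgumentError):
            enrichment_test(classified, "AA")

    def test_two_sided_capped(self):
        classified = self._classified(["AA", "CE"], ["AA", "CE"])
        res = enrichment_test(classified, "AA")
        assert 0 <= res.p_two_sided <= 1

    def test_benjamini_hochberg(self):
        pvals = [0.01, 0.04, 0.03, 0.5]
        q = benjamini_hochberg(pvals)
        # classic worked example: sorted p (0.01,0.03,0.04,0.5) ->
        # q = (0.04, 0.053..., 0.053..., 0.5)
        assert q[0] == pytest.approx(0.04)
        assert q[1] == pytest.approx(0.04 * 4 / 3, rel=1e-9)
        assert q[3] == pytest.approx(0.5)


class TestDifferentialIR:
    def _rec(self, start, ratio, depth=50, gene="g1"):
        return IRRecord(
            chrom="chr1", start=start, end=start + 100, strand="+",
            gene_id=gene, ir_ratio=ratio, depth=depth,
        )

    def test_identical_tables_no_calls(self):
        a = [self._rec(0, 0.3), self._rec(200, 0.8)]
        s = differential_ir(a, a, min_delta=0.1, min_depth=10)
        assert s.n_gained_genes == 0 and s.n_lost_genes == 0

    def test_delta_exactly_at_threshold_not_called(self):
        a = [self._rec(0, 0.30)]
        b = [self._rec(0, 0.40)]  # delta exactly 0.1
        s = differential_ir(a, b, min_delta=0.1, min_depth=10)
        assert s.n_gained_genes == 0

    def test_depth_gate(self):
        a = [self._rec(0, 0.1, depth=5)]
        b = [self._rec(0, 0.9, depth=50)]
        s = differential_ir(a, b, min_delta=0.1, min_depth=10)
        assert s.n_gained_genes == 0

    def test_twenty_intron_fixture(self):
        # 10 genes x 2 introns; hand-computed calls with min_delta=0.2,
        # min_depth=10
        a, b = [], []
        expected_gain, expected_loss = set(), set()
        for g in range(10):
            gene = f"g{g:02d}"
            base = g * 1000
            # intron 1: delta = +0.25 for even genes (gain), 0 otherwise
            d1 = 0.25 if g % 2 == 0 else 0.0
            a.append(self._rec(base, 0.3, depth=30, gene=gene))
            b.append(self._rec(base, 0.3 + d1, depth=30, gene=gene))
            # intron 2: delta = -0.5 for g in {1, 3}, depth too low for 3
            d2 = -0.5 if g in (1, 3) else 0.0
            depth = 5 if g == 3 else 40
            a.append(self._rec(base + 500, 0.6, depth=depth, gene=gene))
            b.append(self._rec(base + 500, 0.6 + d2, depth=depth, gene=gene))
            if g % 2 == 0:
                expected_gain.add(gene)
            if g == 1:
                expected_loss.add(gene)
        s = differential_ir(a, b, min_delta=0.2, min_depth=10)
        assert set(s.gained_genes) == expected_gain
        assert set(s.lost_genes) == expected_loss
        assert len(s.gained_introns) == 5 and len(s.lost_introns) == 1

    def test_gene_summarized_by_most_extreme_intron(self):
        a = [self._rec(0, 0.2, gene="g"), self._rec(500, 0.9, gene="g")]
        b = [self._rec(0, 0.5, gene="g"), self._rec(500, 0.2, gene="g")]
        # +0.3 gain vs -0.7 loss: loss is more extreme
        s = differential_ir(a, b, min_delta=0.1, min_depth=10)
        assert s.lost_genes == ["g"] and s.gained_genes == []

    def test_key_mismatch_rejected(self):
        a = [self._rec(0, 0.3)]
        b = [self._rec(999, 0.3)]
        with pytest.raises(ConsistencyError):
            differential_ir(a, b, min_delta=0.1, min_depth=10)

    def test_invalid_min_delta(self):
        a = [self._rec(0, 0.3)]
        with pytest.raises(InvalidArgumentError):
            differential_ir(a, a, min_delta=0.0, min_depth=10)
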