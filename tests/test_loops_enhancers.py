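import numpy as np
import pytest

from hrrscan.enhancers import (
    Enhancer,
    TargetAssignment,
    assign_presumed_targets,
    compare_enrichment_scores,
    define_core_regions,
    define_hrr_enhancers,
)
from hrrscan.intervals import GenomicInterval
from hrrscan.loops import (
    EnhancerGeneLink,
    Loop,
    TssRecord,
    assign_targets,
    count_ep_pairs,
    filter_loops,
    promoter_windows,
)
from tests.oracles import double_loop_assign


def _loop(s1, e1, s2, e2, c1="chr1", c2=None):
    return Loop(
        GenomicInterval(c1, s1, e1), GenomicInterval(c2 or c1, s2, e2), q=0.01
    )


class TestFilterLoops:
    def test_fifteen_kb_midpoint_distance_removed(self):
        lp = _loop(10_000, 15_000, 25_000, 30_000)  # midpoints 12.5k / 27.5k
        assert lp.distance == 15_000
        assert filter_loops([lp]) == []

    def test_exactly_twenty_kb_kept(self):
        lp = _loop(10_000, 15_000, 30_000, 35_000)  # midpoints 12.5k / 32.5k
        assert lp.distance == 20_000
        assert filter_loops([lp]) == [lp]

    def test_inter_chromosomal_removed(self):
        lp = _loop(0, 5_000, 100_000, 105_000, c1="chr1", c2="chr2")
        assert filter_loops([lp]) == []

    def test_above_two_mb_removed(self):
        lp = _loop(0, 5_000, 2_500_000, 2_505_000)
        assert filter_loops([lp]) == []


class TestPromoterWindows:
    def test_plus_strand(self):
        w = promoter_windows([TssRecord("g", "chr1", 100_000, "+")])
        assert w["g"] == GenomicInterval("chr1", 80_000, 105_000)

    def test_minus_strand_reflection(self):
        w = promoter_windows([TssRecord("g", "chr1", 100_000, "-")])
        assert w["g"] == GenomicInterval("chr1", 95_000, 120_000)

    def test_clipping_at_chromosome_start(self):
        w = promoter_windows([TssRecord("g", "chr1", 1_000, "+")])
        assert w["g"] == GenomicInterval("chr1", 0, 6_000)

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            promoter_windows([TssRecord("g", "chr1", 1_000, ".")])


class TestAssignTargets:
    def test_planted_link_found_and_anchor_order_symmetric(self):
        enh = [("E_001", GenomicInterval("chr1", 50_000, 55_000))]
        prom = {"geneA": GenomicInterval("chr1", 180_000, 205_000)}
        lp = _loop(50_000, 55_000, 190_000, 195_000)
        swapped = Loop(lp.anchor2, lp.anchor1, lp.q)
        for loop in (lp, swapped):
            links = assign_targets([loop], enh, prom)
            assert [(l.enhancer_id, l.gene, l.n_loops) for l in links] == [
                ("E_001", "geneA", 1)
            ]

    def test_both_anchors_in_promoters_no_link(self):
        enh = [("E_001", GenomicInterval("chr1", 50_000, 55_000))]
        prom = {
            "geneA": GenomicInterval("chr1", 180_000, 205_000),
            "geneB": GenomicInterval("chr1", 280_000, 305_000),
        }
        lp = _loop(190_000, 195_000, 290_000, 295_000)
        assert assign_targets([lp], enh, prom) == []

    def test_random_loops_match_double_loop_oracle(self, rng):
        enh = [
            (f"E_{i:03d}", GenomicInterval("chr1", int(s := rng.integers(0, 900_000)), int(s + rng.integers(500, 5_000))))
            for i in range(8)
        ]
        prom = {
            f"g{j}": GenomicInterval("chr1", int(s := rng.integers(0, 900_000)), int(s + 25_000))
            for j in range(10)
        }
        loops = [
            _loop(
                int(a := rng.integers(0, 950_000)), int(a + 5_000),
                int(b := rng.integers(0, 950_000)), int(b + 5_000),
            )
            for _ in range(50)
        ]
        got = {(l.enhancer_id, l.gene) for l in assign_targets(loops, enh, prom)}
        assert got == double_loop_assign(loops, enh, prom)


class TestCountEpPairs:
    def test_empty_loop_set(self):
        assert count_ep_pairs([], [], []) == (0, 0)

    def test_all_ep_by_construction(self):
        enh = [GenomicInterval("chr1", 10_000, 12_000)]
        tss = [TssRecord("g", "chr1", 500_000, "+")]
        loops = [_loop(10_000, 12_000, 498_000, 502_000) for _ in range(5)]
        assert count_ep_pairs(loops, enh, tss) == (5, 5)

    def test_random_loops_match_scan_oracle(self, rng):
        enh = [
            GenomicInterval("chr1", int(s := rng.integers(0, 900_000)), int(s + 2_000))
            for _ in range(10)
        ]
        tss = [
            TssRecord(f"g{j}", "chr1", int(rng.integers(10_000, 900_000)), "+")
            for j in range(10)
        ]
        loops = [
            _loop(
                int(a := rng.integers(0, 950_000)), int(a + 5_000),
                int(b := rng.integers(0, 950_000)), int(b + 5_000),
            )
            for _ in range(100)
        ]
        n, n_ep = count_ep_pairs(loops, enh, tss)
        assert n == 100
        prom = [GenomicInterval(t.chrom, t.tss - 3_000, t.tss + 3_000) for t in tss]
        expected = 0
        for lp in loops:
            ok = False
            for a, b in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
                if any(a.overlaps(e) for e in enh) and any(b.overlaps(p) for p in prom):
                    ok = True
            expected += ok
        assert n_ep == expected


class TestDefineHrrEnhancers:
    def test_one_bp_overlap_is_associated(self):
        hrrs = [("HRR_0", "DEL", GenomicInterval("chr1", 4_999, 6_000))]
        peaks = [GenomicInterval("chr1", 0, 5_000)]
        (enh,) = define_hrr_enhancers(hrrs, peaks)
        assert enh.hrr_associated and enh.hrr_links == [("HRR_0", "DEL")]

    def test_no_overlap_is_unrelated(self):
        hrrs = [("HRR_0", "DEL", GenomicInterval("chr1", 5_000, 6_000))]
        peaks = [GenomicInterval("chr1", 0, 5_000)]
        (enh,) = define_hrr_enhancers(hrrs, peaks)
        assert not enh.hrr_associated

    def test_random_peaks_match_pairwise_scan(self, rng):
        hrrs = [
            (f"H{i}", "DEL", GenomicInterval("chr1", int(s := rng.integers(0, 90_000)), int(s + rng.integers(100, 3_000))))
            for i in range(40)
        ]
        peaks = [
            GenomicInterval("chr1", int(s := rng.integers(0, 90_000)), int(s + rng.integers(100, 3_000)))
            for _ in range(40)
        ]
        out = define_hrr_enhancers(hrrs, peaks)
        sorted_peaks = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
        for enh, peak in zip(out, sorted_peaks):
            expected = {h for h, _, iv in hrrs if peak.overlaps(iv)}
            assert {h for h, _ in enh.hrr_links} == expected

    def test_ids_assigned_in_genomic_order(self):
        peaks = [GenomicInterval("chr2", 0, 100), GenomicInterval("chr1", 50, 150)]
        out = define_hrr_enhancers([], peaks)
        assert [e.enhancer_id for e in out] == ["E_001", "E_002"]
        assert out[0].interval.chrom == "chr1"


class TestDefineCoreRegions:
    def test_intersection_arithmetic(self):
        enh = Enhancer("E_001", GenomicInterval("chr1", 0, 5_000), [("h", "DEL")])
        out = define_core_regions(
            [enh],
            h3k4me1=[GenomicInterval("chr1", 1_000, 6_000)],
            atac=[GenomicInterval("chr1", 2_000, 2_500)],
        )
        assert out == [enh]
        assert enh.core_regions == [GenomicInterval("chr1", 2_000, 2_500)]

    def test_no_h3k4me1_means_ineligible(self):
        enh = Enhancer("E_001", GenomicInterval("chr1", 0, 5_000), [("h", "DEL")])
        out = define_core_regions([enh], h3k4me1=[], atac=[GenomicInterval("chr1", 0, 500)])
        assert out == [] and enh.core_regions == []

    def test_two_atac_peaks_give_two_cores(self):
        enh = Enhancer("E_001", GenomicInterval("chr1", 0, 5_000), [("h", "DEL")])
        define_core_regions(
            [enh],
            h3k4me1=[GenomicInterval("chr1", 0, 5_000)],
            atac=[GenomicInterval("chr1", 100, 300), GenomicInterval("chr1", 4_000, 5_500)],
        )
        assert enh.core_regions == [
            GenomicInterval("chr1", 100, 300),
            GenomicInterval("chr1", 4_000, 5_000),  # clipped at enhancer end
        ]
        assert sum(len(c) for c in enh.core_regions) <= len(enh.interval)


class TestCompareEnrichmentScores:
    def _assignments(self, hrr_genes, null_genes):
        return [
            TargetAssignment("E_001", g, 0, "DEL") for g in hrr_genes
        ] + [TargetAssignment("E_999", g, 0, "HRR-unrelated") for g in null_genes]

    def test_exact_worked_example(self):
        scores = {"a": 1, "b": 2, "c": 3, "x": 4, "y": 5, "z": 6}
        res = compare_enrichment_scores(
            self._assignments(["a", "b", "c"], ["x", "y", "z"]), scores
        )
        (r,) = res
        assert r.u_statistic == 0
        assert r.p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        scores = {"a": 1.0, "b": 2.0, "x": 1.0, "y": 2.0}
        (r,) = compare_enrichment_scores(
            self._assignments(["a", "b"], ["x", "y"]), scores
        )
        assert r.p_value == pytest.approx(1.0)

    def test_against_permutation_oracle(self, rng):
        hrr_genes = [f"h{i}" for i in range(40)]
        null_genes = [f"n{i}" for i in range(160)]
        scores = {g: float(rng.normal()) for g in hrr_genes + null_genes}
        for g in hrr_genes:
            scores[g] += 0.5
        (r,) = compare_enrichment_scores(
            self._assignments(hrr_genes, null_genes), scores
        )
        # permutation oracle on the rank-sum statistic
        from scipy.stats import rankdata

        pooled = np.array([scores[g] for g in hrr_genes + null_genes])
        n1 = len(hrr_genes)
        ranks = rankdata(pooled)
        obs = abs(ranks[:n1].sum() - n1 * (len(pooled) + 1) / 2)
        n_perm, hits = 4000, 0
        for _ in range(n_perm):
            perm = rng.permutation(ranks)
            if abs(perm[:n1].sum() - n1 * (len(pooled) + 1) / 2) >= obs - 1e-9:
                hits += 1
        p_mc = hits / n_perm
        se = max(np.sqrt(p_mc * (1 - p_mc) / n_perm), 1 / n_perm)
        assert abs(r.p_value - p_mc) <= 4 * se + 1e-3

    def test_monotone_transform_invariance(self, rng):
        genes = {f"g{i}": float(rng.normal()) for i in range(30)}
        hrr = list(genes)[:10]
        null = list(genes)[10:]
        a = compare_enrichment_scores(self._assignments(hrr, null), genes)
        warped = {g: np.exp(3 * v) for g, v in genes.items()}
        b = compare_enrichment_scores(self._assignments(hrr, null), warped)
        assert a[0].p_value == pytest.approx(b[0].p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="HRR-unrelated"):
            compare_enrichment_scores(
                [TargetAssignment("E_001", "a", 0, "DEL")], {"a": 1.0}
            )


class TestAssignPresumedTargets:
    def test_window_boundary_inclusive_at_one_mb(self):
        enh = Enhancer("E_001", GenomicInterval("chr1", 2_000_000, 2_001_000), [("h", "DEL")])
        tss_in = TssRecord("near", "chr1", 1_000_000, "+")  # exactly 1 Mb from start
        tss_out = TssRecord("far", "chr1", 999_999, "+")
        out = assign_presumed_targets([enh], [tss_in, tss_out])
        assert [a.gene for a in out] == ["near"]

    def test_gene_shared_with_unrelated_kept_in_hrr_group_only(self):
        hrr_enh = Enhancer("E_001", GenomicInterval("chr1", 10_000, 11_000), [("h", "DUP")])
        plain = Enhancer("E_002", GenomicInterval("chr1", 50_000, 51_000), [])
        tss = [TssRecord("shared", "chr1", 30_000, "+")]
        out = assign_presumed_targets([hrr_enh, plain], tss)
        assert {(a.gene, a.group) for a in out} == {("shared", "DUP")}
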