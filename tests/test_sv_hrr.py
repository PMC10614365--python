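import numpy as np
import pytest

from hrrscan.intervals import Genome, GenomicInterval
from hrrscan.sv_hrr import (
    HrrRegion,
    SvCall,
    WindowTrack,
    call_sv_hrrs,
    count_donors,
    dual_consensus,
    filter_sv,
    make_windows,
    merge_across_types,
    seed_and_merge,
)
from tests.oracles import (
    sv_filter_scan,
    sv_grow_regions,
    sv_window_donors,
)


def _random_calls(rng, n, n_donors=20, chrom_len=1_000_000):
    calls = []
    for _ in range(n):
        donor = f"D{rng.integers(0, n_donors)}"
        caller = ["manta_like", "gridss_like"][rng.integers(0, 2)]
        sv_type = ["DEL", "DUP", "INV", "TRA"][rng.integers(0, 4)]
        if sv_type == "TRA":
            p1 = int(rng.integers(0, chrom_len))
            p2 = int(rng.integers(0, chrom_len))
            calls.append(SvCall(donor, caller, "TRA", "chr1", p1, "chr2", p2))
        else:
            length = int(np.exp(rng.uniform(np.log(50), np.log(2_000_000))))
            length = min(length, chrom_len - 1)
            p1 = int(rng.integers(0, chrom_len - length))
            chrom = ["chr1", "chr2"][rng.integers(0, 2)]
            calls.append(SvCall(donor, caller, sv_type, chrom, p1, chrom, p1 + length))
    return calls


class TestSvCall:
    def test_invariants(self):
        with pytest.raises(ValueError):
            SvCall("d", "c", "DEL", "chr1", 100, "chr2", 200)
        with pytest.raises(ValueError):
            SvCall("d", "c", "DEL", "chr1", 200, "chr1", 100)
        with pytest.raises(ValueError):
            SvCall("d", "c", "TRA", "chr1", 100, "chr1", 200)
        assert SvCall("d", "c", "TRA", "chr1", 1, "chr2", 2).length is None


class TestFilterSv:
    def test_one_mb_boundary_inclusive_keep(self):
        keep = SvCall("d", "c", "DEL", "chr1", 0, "chr1", 1_000_000)
        drop = SvCall("d", "c", "DEL", "chr1", 0, "chr1", 1_000_001)
        assert filter_sv([keep, drop]) == [keep]

    def test_tra_exempt(self):
        tra = SvCall("d", "c", "TRA", "chr1", 5, "chr2", 5)
        assert filter_sv([tra]) == [tra]

    def test_mixed_list_against_scan_oracle(self, rng):
        calls = _random_calls(rng, 20)
        assert filter_sv(calls) == sv_filter_scan(calls)


class TestMakeWindows:
    def test_window_arithmetic(self):
        g = Genome({"c": 1200})
        track = make_windows(g, "INV", window_size=1000, step=200)
        assert track.windows["c"] == [
            (0, 1000), (200, 1200), (400, 1200), (600, 1200), (800, 1200), (1000, 1200),
        ]

    def test_short_chromosome_clipped(self):
        g = Genome({"c": 500})
        track = make_windows(g, "INV", window_size=1000, step=200)
        assert track.windows["c"] == [(0, 500), (200, 500), (400, 500)]

    def test_type_defaults(self):
        g = Genome({"c": 100_000})
        del_track = make_windows(g, "DEL")
        tra_track = make_windows(g, "TRA")
        assert (del_track.window_size, del_track.step) == (10_000, 2_000)
        assert (tra_track.window_size, tra_track.step) == (1_000, 200)


class TestCountDonors:
    def test_donor_counted_once_per_window(self):
        g = Genome({"c": 20_000})
        track = make_windows(g, "DEL")
        calls = [
            SvCall("d1", "x", "DEL", "c", 100, "c", 300),
            SvCall("d1", "x", "DEL", "c", 400, "c", 600),
            SvCall("d1", "x", "DEL", "c", 700, "c", 900),
        ]
        count_donors(track, calls)
        assert track.donors["c"][0] == {"d1"}

    def test_tra_contributes_on_both_chromosomes(self):
        g = Genome({"chr1": 5_000, "chr2": 5_000})
        track = make_windows(g, "TRA")
        count_donors(track, [SvCall("d1", "x", "TRA", "chr1", 500, "chr2", 4_500)])
        assert any("d1" in s for s in track.donors["chr1"])
        assert any("d1" in s for s in track.donors["chr2"])

    @pytest.mark.parametrize("sv_type", ["DEL", "INV", "TRA"])
    def test_random_calls_against_scan_oracle(self, rng, sv_type):
        g = Genome({"chr1": 200_000, "chr2": 200_000})
        calls = [c for c in _random_calls(rng, 100, chrom_len=200_000) if c.sv_type == sv_type]
        track = make_windows(g, sv_type)
        count_donors(track, calls)
        oracle = sv_window_donors(g, sv_type, calls, track.window_size, track.step)
        for chrom in g.chroms:
            got = track.donors[chrom]
            exp = [d for _, _, d in oracle[chrom]]
            assert got == exp


def _track_from_counts(counts_by_window, window=1000, step=200):
    """Build a WindowTrack on one chromosome with prescribed donor sets."""
    n = len(counts_by_window)
    length = (n - 1) * step + window
    g = Genome({"c": length})
    track = make_windows(g, "INV", window_size=window, step=step)
    for i, donors in enumerate(counts_by_window):
        track.donors["c"][i] = set(donors)
    return track


class TestSeedAndMerge:
    def test_single_isolated_seed_window(self):
        donors = [set() for _ in range(9)]
        donors[4] = {f"d{i}" for i in range(12)}
        track = _track_from_counts(donors)
        regions = seed_and_merge(track)
        assert len(regions) == 1
        r = regions[0]
        assert r.interval == GenomicInterval("c", 4 * 200, 4 * 200 + 1000)
        assert r.donor_count == 12

    def test_plateau_below_candidate_threshold(self):
        # every window holds 4 donors drawn from 9 distinct donors total
        pool = [f"d{i}" for i in range(9)]
        donors = [set(pool[(i % 3) * 3 : (i % 3) * 3 + 4] + pool[:1]) for i in range(5)]
        all_distinct = set().union(*donors)
        assert len(all_distinct) == 9
        track = _track_from_counts(donors)
        assert seed_and_merge(track) == []

    def test_empty_track(self):
        track = _track_from_counts([set() for _ in range(5)])
        assert seed_and_merge(track) == []

    def test_extension_stops_at_empty_window(self):
        donors = [
            {"a"}, set(), {"d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8", "d9"},
            {"d10", "x"}, set(),
        ]
        track = _track_from_counts(donors)
        regions = seed_and_merge(track)
        assert len(regions) == 1
        assert regions[0].interval.start == 2 * 200
        assert regions[0].donor_count == 11


class TestDualConsensus:
    def _region(self, start, end, donors, label=""):
        return HrrRegion(
            GenomicInterval("c", start, end), "DEL", frozenset(donors), label
        )

    def test_identical_regions_labelled_dual(self):
        a = [self._region(0, 1000, {"d1"})]
        b = [self._region(0, 1000, {"d2"})]
        out = dual_consensus(a, b, "manta_like", "gridss_like")
        assert len(out) == 1
        assert out[0].caller_label == "Dual"
        assert out[0].donor_ids == {"d1", "d2"}

    def test_single_caller_region_keeps_label(self):
        out = dual_consensus([self._region(0, 1000, {"d1"})], [], "manta_like", "gridss_like")
        assert out[0].caller_label == "manta_like"

    def test_random_regions_against_merge_then_attribute_oracle(self, rng):
        from tests.oracles import union_find_merge

        regions = []
        for _ in range(30):
            s = int(rng.integers(0, 5000))
            regions.append(
                self._region(s, s + int(rng.integers(100, 800)), {f"d{rng.integers(0, 10)}"})
            )
        half = len(regions) // 2
        out = dual_consensus(regions[:half], regions[half:], "A", "B")
        oracle = union_find_merge([r.interval for r in regions])
        assert [r.interval for r in out] == [iv for iv, _ in oracle]
        for r, (_, members) in zip(out, oracle):
            callers = {"A" if m < half else "B" for m in members}
            assert r.caller_label == ("Dual" if len(callers) == 2 else callers.pop())
            assert r.donor_ids == frozenset().union(*(regions[m].donor_ids for m in members))


class TestMergeAcrossTypes:
    def test_disjoint_carrier_sets_sum(self):
        del_r = HrrRegion(GenomicInterval("c", 0, 1000), "DEL", frozenset(f"a{i}" for i in range(10)), "Dual")
        dup_r = HrrRegion(GenomicInterval("c", 500, 1500), "DUP", frozenset(f"b{i}" for i in range(10)), "Dual")
        calls = [
            SvCall(f"a{i}", "x", "DEL", "c", 10, "c", 900) for i in range(10)
        ] + [
            SvCall(f"b{i}", "x", "DUP", "c", 600, "c", 1400) for i in range(10)
        ]
        out = merge_across_types({"DEL": [del_r], "DUP": [dup_r]}, calls)
        assert len(out) == 1
        assert out[0].sv_type == "MERGED"
        assert out[0].donor_count == 20
        assert out[0].contributing_types == ("DEL", "DUP")

    def test_shared_carriers_counted_once(self):
        donors = frozenset(f"d{i}" for i in range(10))
        del_r = HrrRegion(GenomicInterval("c", 0, 1000), "DEL", donors, "Dual")
        dup_r = HrrRegion(GenomicInterval("c", 500, 1500), "DUP", donors, "Dual")
        calls = [SvCall(d, "x", "DEL", "c", 10, "c", 900) for d in donors] + [
            SvCall(d, "x", "DUP", "c", 600, "c", 1400) for d in donors
        ]
        out = merge_across_types({"DEL": [del_r], "DUP": [dup_r]}, calls)
        assert out[0].donor_count == 10

    def test_non_overlapping_pass_through(self):
        a = HrrRegion(GenomicInterval("c", 0, 1000), "DEL", frozenset(["d"]), "Dual")
        b = HrrRegion(GenomicInterval("c", 5000, 6000), "DUP", frozenset(["e"]), "Dual")
        out = merge_across_types(
            {"DEL": [a], "DUP": [b]},
            [
                SvCall("d", "x", "DEL", "c", 1, "c", 500),
                SvCall("e", "x", "DUP", "c", 5100, "c", 5900),
            ],
        )
        assert len(out) == 2
        assert {o.interval.start for o in out} == {0, 5000}


class TestEndToEndOracle:
    def test_caller_matches_brute_force_on_random_instances(self):
        """Sliding-window caller vs enumerate-and-grow oracle, 20 instances."""
        g = Genome({"chr1": 1_000_000, "chr2": 1_000_000})
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            calls = filter_sv(_random_calls(rng, int(rng.integers(20, 100))))
            for sv_type in ("DEL", "DUP", "INV", "TRA"):
                subset = [c for c in calls if c.sv_type == sv_type]
                track = make_windows(g, sv_type)
                count_donors(track, subset)
                got = seed_and_merge(track, 2, 3)
                oracle = sv_grow_regions(
                    sv_window_donors(g, sv_type, subset, track.window_size, track.step),
                    g.chroms, seed_min=2, cand_min=3,
                )
                assert [
                    (r.interval.chrom, r.interval.start, r.interval.end, r.donor_ids)
                    for r in got
                ] == oracle

    def test_monotonicity_adding_a_donor_never_decreases_counts(self, rng):
        g = Genome({"chr1": 500_000, "chr2": 500_000})
        calls = [c for c in _random_calls(rng, 60, chrom_len=500_000) if c.sv_type == "DEL"]
        track = make_windows(g, "DEL")
        count_donors(track, calls)
        before = {c: [len(s) for s in track.donors[c]] for c in g.chroms}
        extra = SvCall("NEW", "x", "DEL", "chr1", 100_000, "chr1", 150_000)
        track2 = make_windows(g, "DEL")
        count_donors(track2, calls + [extra])
        for c in g.chroms:
            after = [len(s) for s in track2.donors[c]]
            assert all(a >= b for a, b in zip(after, before[c]))
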