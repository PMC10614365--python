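"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written as the most naive possible computation — full
scans, exhaustive enumeration, union-find — and deliberately shares no code
with the package's optimized paths.
"""

from __future__ import annotations

import re

from hrrscan.intervals import GenomicInterval


# --- interval algebra -------------------------------------------------------


def union_find_merge(intervals, min_overlap=1):
    """Pairwise union-find merge; returns sorted (interval, member set)."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom:
                continue
            if min(a.end, b.end) - max(a.start, b.start) >= min_overlap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    out = []
    for members in groups.values():
        chrom = intervals[next(iter(members))].chrom
        start = min(intervals[i].start for i in members)
        end = max(intervals[i].end for i in members)
        out.append((GenomicInterval(chrom, start, end), members))
    return sorted(out, key=lambda t: (t[0].chrom, t[0].start))


def scan_overlap_query(query, subjects):
    return [
        i
        for i, s in enumerate(subjects)
        if s.chrom == query.chrom and s.start < query.end and query.start < s.end
    ]


# --- SV-HRR caller ----------------------------------------------------------


def sv_window_donors(genome, sv_type, calls, size, step):
    """Naive per-window donor sets: full scan of every call per window."""
    out = {}
    for chrom, length in genome.lengths.items():
        wins = []
        s = 0
        while s < length:
            e = min(s + size, length)
            donors = set()
            for c in calls:
                if c.sv_type != sv_type:
                    continue
                if sv_type in ("DEL", "DUP"):
                    if c.chrom1 == chrom and c.pos1 < e and s < c.pos2:
                        donors.add(c.donor_id)
                else:
                    for ch, p in ((c.chrom1, c.pos1), (c.chrom2, c.pos2)):
                        if ch == chrom and s <= p < e:
                            donors.add(c.donor_id)
            wins.append((s, e, donors))
            s += step
        out[chrom] = wins
    return out


def sv_grow_regions(window_donors, chrom_order, seed_min=4, cand_min=10):
    """Exhaustive enumerate-and-grow: repeated global maximum, naive extension.

    Returns candidate regions as (chrom, start, end, frozenset(donors)).
    """
    consumed = {c: [False] * len(w) for c, w in window_donors.items()}
    regions = []
    rank = {c: i for i, c in enumerate(chrom_order)}
    while True:
        best = None
        for chrom in sorted(window_donors, key=lambda c: rank[c]):
            for i, (s, e, donors) in enumerate(window_donors[chrom]):
                if consumed[chrom][i] or len(donors) < seed_min:
                    continue
                key = (-len(donors), rank[chrom], s)
                if best is None or key < best[0]:
                    best = (key, chrom, i)
        if best is None:
            break
        _, chrom, i = best
        wins = window_donors[chrom]
        lo = hi = i
        while lo - 1 >= 0 and not consumed[chrom][lo - 1] and len(wins[lo - 1][2]) >= 1:
            lo -= 1
        while hi + 1 < len(wins) and not consumed[chrom][hi + 1] and len(wins[hi + 1][2]) >= 1:
            hi += 1
        donors = set()
        for j in range(lo, hi + 1):
            consumed[chrom][j] = True
            donors |= wins[j][2]
        if len(donors) >= cand_min:
            regions.append((chrom, wins[lo][0], wins[hi][1], frozenset(donors)))
    return sorted(regions, key=lambda r: (rank[r[0]], r[1]))


def sv_filter_scan(calls, max_len=1_000_000):
    out = []
    for c in calls:
        if c.sv_type == "TRA":
            out.append(c)
        elif c.pos2 - c.pos1 <= max_len:
            out.append(c)
    return out


# --- guide enumeration ------------------------------------------------------

_RC = str.maketrans("ACGT", "TGCA")


def regex_guide_scan(seq, core_start, core_end, bin_start, bin_end):
    """All (protospacer, strand, cut) candidates via regex on both strands.

    Eligibility (TTTT/N/GC band) is NOT applied; the caller filters.
    """
    cands = []
    for m in re.finditer(r"(?=([ACGTN]{20})([ACGTN]GG))", seq):
        p = m.start()
        if p < core_start or p + 20 > core_end:
            continue
        cut = p + 17
        if bin_start <= cut < bin_end:
            cands.append((m.group(1), "+", cut))
    for m in re.finditer(r"(?=(CC[ACGTN])([ACGTN]{20}))", seq):
        q = m.start() + 3
        if q < core_start or q + 20 > core_end:
            continue
        cut = q + 3
        if bin_start <= cut < bin_end:
            cands.append((m.group(2).translate(_RC)[::-1], "-", cut))
    return sorted(cands)


# --- loops ------------------------------------------------------------------


def double_loop_assign(loops, enhancers, promoters):
    """Exhaustive double loop over (loop, enhancer, gene), both orderings."""
    pairs = set()
    for lp in loops:
        for eid, eiv in enhancers:
            for gene, piv in promoters.items():
                for pa, ea in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
                    if (
                        pa.chrom == piv.chrom
                        and pa.start < piv.end
                        and piv.start < pa.end
                        and ea.chrom == eiv.chrom
                        and ea.start < eiv.end
                        and eiv.start < ea.end
                    ):
                        pairs.add((eid, gene))
    return pairs
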