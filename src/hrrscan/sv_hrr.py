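"""Sliding-window detection of SV-associated highly recurrent regions (HRRs).

The caller counts, per sliding window, how many distinct donors carry a
qualifying somatic structural variant, then grows regions around recurrence
maxima. Window geometry follows the study design: 10 kb windows with 2 kb
steps for deletions and duplications; 1 kb windows with 200 bp steps for
inversions and translocations, whose recurrence is breakpoint-level.
A window seeding a region must hold >= 4 donors; the merged region is a
candidate HRR when its distinct-donor count reaches >= 10. Regions from the
two SV callers are merged and labelled ``Dual`` when both support them, and
overlapping regions of different SV types are finally merged at patient
level with recurrence recomputed.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field

from .intervals import Genome, GenomicInterval, merge_intervals, to_report_coords

SV_TYPES = ("DEL", "DUP", "INV", "TRA")
INTERVAL_TYPES = ("DEL", "DUP")  # counted by interval overlap
BREAKEND_TYPES = ("INV", "TRA")  # counted by breakend containment

#: (window_size, step) per SV type
DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {
    "DEL": (10_000, 2_000),
    "DUP": (10_000, 2_000),
    "INV": (1_000, 200),
    "TRA": (1_000, 200),
}

MAX_SV_LENGTH = 1_000_000  # fragments strictly over 1 Mb are removed


@dataclass(frozen=True)
class SvCall:
    """One somatic structural-variant record.

    DEL/DUP/INV have both breakends on one chromosome with pos1 < pos2;
    TRA spans two chromosomes and has no fragment length.
    """

    donor_id: str
    caller: str
    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type == "TRA":
            if self.chrom1 == self.chrom2:
                raise ValueError("TRA must span two chromosomes")
        else:
            if self.chrom1 != self.chrom2:
                raise ValueError(f"{self.sv_type} breakends must share a chromosome")
            if not self.pos1 < self.pos2:
                raise ValueError(f"{self.sv_type} requires pos1 < pos2")

    @property
    def length(self) -> int | None:
        if self.sv_type == "TRA":
            return None
        return self.pos2 - self.pos1


@dataclass
class WindowTrack:
    """Sliding windows of one SV type with per-window donor-id sets."""

    sv_type: str
    window_size: int
    step: int
    chroms: list[str]
    chrom_lengths: dict[str, int]
    # per chrom: list of (start, end) windows, ordered by start
    windows: dict[str, list[tuple[int, int]]]
    donors: dict[str, list[set[str]]]


@dataclass
class HrrRegion:
    """A merged recurrent interval with donor support and caller label."""

    interval: GenomicInterval
    sv_type: str
    donor_ids: frozenset[str]
    caller_label: str
    seed_window_count: int = 0
    contributing_types: tuple[str, ...] = field(default_factory=tuple)

    @property
    def donor_count(self) -> int:
        return len(self.donor_ids)


def filter_sv(calls: list[SvCall], max_length: int = MAX_SV_LENGTH) -> list[SvCall]:
    """Drop intra-chromosomal SVs with fragment length over ``max_length``.

    The boundary is inclusive-keep (exactly 1 Mb is retained); translocations
    have no fragment length and pass through. Insertions never reach this
    stage: they are rejected when call sets are parsed.
    """
    out = []
    for c in calls:
        if c.sv_type == "TRA" or c.length <= max_length:
            out.append(c)
    return out


def make_windows(
    genome: Genome, sv_type: str, window_size: int | None = None, step: int | None = None
) -> WindowTrack:
    """Sliding windows at 0, s, 2s, ... while start < chromosome length."""
    if window_size is None or step is None:
        window_size, step = DEFAULT_WINDOWS[sv_type]
    windows: dict[str, list[tuple[int, int]]] = {}
    donors: dict[str, list[set[str]]] = {}
    for chrom, length in genome.lengths.items():
        wins = []
        start = 0
        while start < length:
            wins.append((start, min(start + window_size, length)))
            start += step
        windows[chrom] = wins
        donors[chrom] = [set() for _ in wins]
    return WindowTrack(
        sv_type, window_size, step, genome.chroms, dict(genome.lengths), windows, donors
    )


def _window_range_overlapping(
    track: WindowTrack, chrom: str, start: int, end: int
) -> range:
    """Indices of windows overlapping [start, end) on chrom (regular grid)."""
    wins = track.windows.get(chrom)
    if not wins:
        return range(0)
    s, w = track.step, track.window_size
    # window i = [i*s, i*s + w): overlaps iff i*s < end and i*s + w > start
    lo = max(0, (start - w) // s + 1)
    hi = min(len(wins), (end - 1) // s + 1)
    return range(lo, max(lo, hi))


def count_donors(
    track: WindowTrack, calls: list[SvCall], breakend_only: bool = False
) -> WindowTrack:
    """Add each donor to every window its SV touches.

    DEL/DUP: the donor joins all windows overlapping the fragment
    [pos1, pos2) (or only the breakend windows when ``breakend_only``).
    INV/TRA: the donor joins the windows containing either breakend position
    (TRA contributes on both chromosomes). A donor is counted once per
    window regardless of call multiplicity.
    """
    for c in calls:
        if c.sv_type != track.sv_type:
            raise ValueError(f"call type {c.sv_type} != track type {track.sv_type}")
        if track.sv_type in INTERVAL_TYPES and not breakend_only:
            for i in _window_range_overlapping(track, c.chrom1, c.pos1, c.pos2):
                track.donors[c.chrom1][i].add(c.donor_id)
        else:
            for chrom, pos in ((c.chrom1, c.pos1), (c.chrom2, c.pos2)):
                for i in _window_range_overlapping(track, chrom, pos, pos + 1):
                    track.donors[chrom][i].add(c.donor_id)
    return track


def seed_and_merge(
    track: WindowTrack,
    seed_min_donors: int = 4,
    candidate_min_donors: int = 10,
    extend_min_donors: int = 1,
) -> list[HrrRegion]:
    """Grow candidate regions around donor-count maxima.

    Iteratively picks the unconsumed window with the largest donor count
    (ties break to the leftmost window on the lowest-ordered chromosome);
    stops when the maximum falls below ``seed_min_donors``. The seed is
    extended across step-adjacent windows on both sides while each holds at
    least ``extend_min_donors`` donors and is unconsumed. The merged interval
    is the union of consumed windows; it is emitted as a candidate HRR iff
    the union of donor ids reaches ``candidate_min_donors``. Consumed windows
    cannot seed or join another region.
    """
    regions: list[HrrRegion] = []
    consumed: dict[str, list[bool]] = {
        chrom: [False] * len(wins) for chrom, wins in track.windows.items()
    }
    # flat candidate list for iterative maxima
    chrom_order = {c: i for i, c in enumerate(track.chroms)}
    entries = [
        (chrom, i)
        for chrom in track.chroms
        for i in range(len(track.windows.get(chrom, [])))
    ]
    while True:
        best = None
        best_key = None
        for chrom, i in entries:
            if consumed[chrom][i]:
                continue
            n = len(track.donors[chrom][i])
            if n < seed_min_donors:
                continue
            key = (-n, chrom_order[chrom], track.windows[chrom][i][0])
            if best_key is None or key < best_key:
                best_key = key
                best = (chrom, i)
        if best is None:
            break
        chrom, i = best
        lo = hi = i
        while (
            lo - 1 >= 0
            and not consumed[chrom][lo - 1]
            and len(track.donors[chrom][lo - 1]) >= extend_min_donors
        ):
            lo -= 1
        nwin = len(track.windows[chrom])
        while (
            hi + 1 < nwin
            and not consumed[chrom][hi + 1]
            and len(track.donors[chrom][hi + 1]) >= extend_min_donors
        ):
            hi += 1
        donor_ids: set[str] = set()
        for j in range(lo, hi + 1):
            consumed[chrom][j] = True
            donor_ids |= track.donors[chrom][j]
        start = track.windows[chrom][lo][0]
        end = track.windows[chrom][hi][1]
        if len(donor_ids) >= candidate_min_donors:
            regions.append(
                HrrRegion(
                    GenomicInterval(chrom, start, end),
                    track.sv_type,
                    frozenset(donor_ids),
                    caller_label="",
                    seed_window_count=hi - lo + 1,
                )
            )
    regions.sort(key=lambda r: (chrom_order[r.interval.chrom], r.interval.start))
    return regions


def dual_consensus(
    hrrs_a: list[HrrRegion],
    hrrs_b: list[HrrRegion],
    caller_a: str,
    caller_b: str,
) -> list[HrrRegion]:
    """Merge per-caller HRRs; overlapping regions from both callers get ``Dual``."""
    tagged = [(r, caller_a) for r in hrrs_a] + [(r, caller_b) for r in hrrs_b]
    if not tagged:
        return []
    sv_types = {r.sv_type for r, _ in tagged}
    if len(sv_types) > 1:
        raise ValueError(f"mixed SV types in consensus: {sorted(sv_types)}")
    sv_type = next(iter(sv_types))
    intervals = [r.interval for r, _ in tagged]
    out = []
    for merged_iv, members in merge_intervals(intervals, min_overlap=1):
        callers = {tagged[i][1] for i in members}
        donor_ids: set[str] = set()
        for i in members:
            donor_ids |= tagged[i][0].donor_ids
        label = "Dual" if len(callers) == 2 else next(iter(callers))
        out.append(
            HrrRegion(
                merged_iv,
                sv_type,
                frozenset(donor_ids),
                caller_label=label,
                seed_window_count=sum(tagged[i][0].seed_window_count for i in members),
            )
        )
    return out


def merge_across_types(
    hrrs_by_type: dict[str, list[HrrRegion]],
    calls: list[SvCall],
) -> list[HrrRegion]:
    """Patient-level merge of overlapping HRRs of any type.

    Overlapping regions are unioned into ``MERGED`` regions recording their
    contributing types; the recurrence count is recomputed as the number of
    distinct donors with at least one qualifying SV touching the merged
    interval, under the same overlap semantics as window counting.
    """
    tagged: list[HrrRegion] = [r for rs in hrrs_by_type.values() for r in rs]
    if not tagged:
        return []
    calls_by_chrom: dict[str, list[SvCall]] = defaultdict(list)
    for c in calls:
        calls_by_chrom[c.chrom1].append(c)
        if c.sv_type == "TRA":
            calls_by_chrom[c.chrom2].append(c)
    out = []
    for merged_iv, members in merge_intervals([r.interval for r in tagged], 1):
        types = tuple(sorted({tagged[i].sv_type for i in members}))
        donors = set()
        for c in calls_by_chrom.get(merged_iv.chrom, ()):
            if c.sv_type in INTERVAL_TYPES:
                hit = c.pos1 < merged_iv.end and merged_iv.start < c.pos2
            else:
                hit = merged_iv.contains_point(c.chrom1, c.pos1) or merged_iv.contains_point(c.chrom2, c.pos2)
            if hit:
                donors.add(c.donor_id)
        label = "Dual" if all(tagged[i].caller_label == "Dual" for i in members) else "Mixed"
        if len(members) == 1:
            only = tagged[next(iter(members))]
            label = only.caller_label
        out.append(
            HrrRegion(
                merged_iv,
                "MERGED",
                frozenset(donors),
                caller_label=label,
                contributing_types=types,
            )
        )
    return out


def call_sv_hrrs(
    calls: list[SvCall],
    genome: Genome,
    seed_min_donors: int = 4,
    candidate_min_donors: int = 10,
    windows: dict[str, tuple[int, int]] | None = None,
) -> dict[str, list[HrrRegion]]:
    """Full per-type SV-HRR calling with dual-caller consensus.

    Returns candidate HRRs per SV type plus a ``MERGED`` cross-type entry.
    ``calls`` should already be length-filtered (see :func:`filter_sv`).
    """
    windows = windows or DEFAULT_WINDOWS
    callers = sorted({c.caller for c in calls}) or ["caller"]
    by_type: dict[str, list[HrrRegion]] = {}
    for sv_type in SV_TYPES:
        per_caller = []
        for caller in callers:
            subset = [c for c in calls if c.sv_type == sv_type and c.caller == caller]
            track = make_windows(genome, sv_type, *windows[sv_type])
            count_donors(track, subset)
            per_caller.append(seed_and_merge(track, seed_min_donors, candidate_min_donors))
        if len(per_caller) == 2:
            by_type[sv_type] = dual_consensus(per_caller[0], per_caller[1], callers[0], callers[1])
        else:
            merged = per_caller[0]
            for r in merged:
                r.caller_label = callers[0]
            by_type[sv_type] = merged
    by_type["MERGED"] = merge_across_types(
        {t: by_type[t] for t in SV_TYPES}, calls
    )
    return by_type


def write_hrr_table(hrrs: list[HrrRegion], path: str) -> None:
    """Write an HRR report table (1-based inclusive printed coordinates)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["chrom", "start_1based", "end", "sv_type", "donor_count", "caller_label", "contributing_types", "donor_ids"]
        )
        for r in hrrs:
            chrom, s1, e1 = to_report_coords(r.interval)
            writer.writerow(
                [
                    chrom,
                    s1,
                    e1,
                    r.sv_type,
                    r.donor_count,
                    r.caller_label,
                    ",".join(r.contributing_types),
                    ",".join(sorted(r.donor_ids)),
                ]
            )
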