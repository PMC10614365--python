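"""Enhancer target assignment from significant chromatin loops.

Loops (HiChIP-style anchor pairs) are filtered to intra-chromosomal
contacts whose anchor-midpoint distance lies in [20 kb, 2 Mb], inclusive.
For target assignment, gene promoters are windows 20 kb upstream to 5 kb
downstream of the TSS; a loop links an enhancer to a gene when one anchor
overlaps the promoter window and the other overlaps the enhancer (both
anchor orderings are checked). A separate, narrower promoter definition
(TSS +/- 3 kb) serves the global enhancer-promoter loop census.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass

from .intervals import GenomicInterval

DEFAULT_MIN_DIST = 20_000
DEFAULT_MAX_DIST = 2_000_000
PROMOTER_UP = 20_000
PROMOTER_DOWN = 5_000
EP_PROMOTER_RADIUS = 3_000


@dataclass(frozen=True)
class Loop:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    q: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.q <= 1:
            raise ValueError("loop q-value must lie in [0, 1]")

    @property
    def intra(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def distance(self) -> float | None:
        """Distance between anchor midpoints; None for inter-chromosomal."""
        if not self.intra:
            return None
        m1 = (self.anchor1.start + self.anchor1.end) / 2
        m2 = (self.anchor2.start + self.anchor2.end) / 2
        return abs(m2 - m1)


@dataclass(frozen=True)
class TssRecord:
    gene: str
    chrom: str
    tss: int
    strand: str


@dataclass
class EnhancerGeneLink:
    enhancer_id: str
    gene: str
    n_loops: int
    shared_anchor: bool = False  # promoter anchor hosts more than one gene


def filter_loops(
    loops: list[Loop],
    min_d: int = DEFAULT_MIN_DIST,
    max_d: int = DEFAULT_MAX_DIST,
) -> list[Loop]:
    """Keep intra-chromosomal loops with midpoint distance in [min_d, max_d]."""
    out = []
    for lp in loops:
        d = lp.distance
        if d is not None and min_d <= d <= max_d:
            out.append(lp)
    return out


def promoter_windows(
    tss_records: list[TssRecord],
    up: int = PROMOTER_UP,
    down: int = PROMOTER_DOWN,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, GenomicInterval]:
    """Strand-aware promoter windows around each TSS, clipped at bounds."""
    out: dict[str, GenomicInterval] = {}
    for rec in tss_records:
        if rec.strand == "+":
            start, end = rec.tss - up, rec.tss + down
        elif rec.strand == "-":
            start, end = rec.tss - down, rec.tss + up
        else:
            raise ValueError(f"gene {rec.gene!r} has unknown strand {rec.strand!r}")
        start = max(0, start)
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[rec.chrom])
        out[rec.gene] = GenomicInterval(rec.chrom, start, end)
    return out


def assign_targets(
    loops: list[Loop],
    enhancers: list[tuple[str, GenomicInterval]],
    promoters: dict[str, GenomicInterval],
) -> list[EnhancerGeneLink]:
    """Loop-supported enhancer -> gene links.

    Emits a link whenever one anchor overlaps (>= 1 bp) a promoter window
    and the other overlaps an enhancer interval; anchor order is
    symmetric. Duplicate (enhancer, gene) pairs collapse with the loop
    count recorded; links whose promoter anchor also hosts other genes are
    flagged ``shared_anchor``.
    """
    pair_loops: dict[tuple[str, str], int] = defaultdict(int)
    pair_shared: dict[tuple[str, str], bool] = defaultdict(bool)
    for lp in loops:
        for prom_anchor, enh_anchor in (
            (lp.anchor1, lp.anchor2),
            (lp.anchor2, lp.anchor1),
        ):
            genes = [g for g, w in promoters.items() if prom_anchor.overlaps(w)]
            if not genes:
                continue
            hit_enh = [eid for eid, iv in enhancers if enh_anchor.overlaps(iv)]
            for eid in hit_enh:
                for g in genes:
                    pair_loops[(eid, g)] += 1
                    if len(genes) > 1:
                        pair_shared[(eid, g)] = True
    return [
        EnhancerGeneLink(eid, g, n, pair_shared[(eid, g)])
        for (eid, g), n in sorted(pair_loops.items())
    ]


def count_ep_pairs(
    loops: list[Loop],
    enhancer_regions: list[GenomicInterval],
    tss_records: list[TssRecord],
    promoter_radius: int = EP_PROMOTER_RADIUS,
) -> tuple[int, int]:
    """Census of loops with a valid enhancer-promoter anchor pair.

    Enhancers here are the externally co-defined (H3K27ac & H3K4me1 & ATAC)
    regions; promoters are TSS +/- ``promoter_radius``. Returns
    (n_loops, n_ep_loops).
    """
    prom = [
        GenomicInterval(r.chrom, max(0, r.tss - promoter_radius), r.tss + promoter_radius)
        for r in tss_records
    ]
    n_ep = 0
    for lp in loops:
        for a, b in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
            if any(a.overlaps(e) for e in enhancer_regions) and any(
                b.overlaps(p) for p in prom
            ):
                n_ep += 1
                break
    return len(loops), n_ep


def read_loop_bedpe(path: str) -> list[Loop]:
    """Read loops from BEDPE: chrom1 start1 end1 chrom2 start2 end2 [name] q."""
    loops = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            q = float(f[7]) if len(f) > 7 else (float(f[6]) if len(f) > 6 and _is_float(f[6]) else 0.0)
            loops.append(
                Loop(
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    GenomicInterval(f[3], int(f[4]), int(f[5])),
                    q,
                )
            )
    return loops


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_tss_table(path: str) -> list[TssRecord]:
    """Read a TSS table: gene, chrom, tss (0-based), strand."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, chrom, tss, strand = line.split("\t")[:4]
            out.append(TssRecord(gene, chrom, int(tss), strand))
    return out


def write_links(links: list[EnhancerGeneLink], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["enhancer_id", "gene", "n_loops", "shared_anchor"])
        for lk in links:
            w.writerow([lk.enhancer_id, lk.gene, lk.n_loops, int(lk.shared_anchor)])
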