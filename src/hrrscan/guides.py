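"""Intersected-tiling sgRNA library design over enhancer core regions.

Each core region is divided into 100 bp bins; all eligible SpCas9 guides
(20 nt protospacer adjacent to an NGG PAM, on either strand, cutting inside
the bin) are scored and the best guide per bin enters the library. Scoring
uses a fully specified deterministic surrogate (GC band plus homopolymer
penalty) behind a pluggable interface, preserving the best-per-bin tiling
structure of the design. Non-targeting controls are random 20-mers verified
to have no exact match anywhere on either genome strand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .intervals import Genome, GenomicInterval
from .mutsig import revcomp

BIN_SIZE = 100
MIN_REMAINDER = 25  # a final partial bin shorter than this merges leftward


@dataclass(frozen=True)
class GuideRecord:
    """A tiling sgRNA (or non-targeting control, enhancer_id == 'NT')."""

    guide_id: str
    enhancer_id: str
    core_id: str
    bin_index: int
    protospacer: str
    pam: str
    strand: str
    cut_site: int  # genomic coordinate of the blunt cut (0-based)
    score: float

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if self.enhancer_id != "NT":
            if len(self.pam) != 3 or self.pam[1:] != "GG":
                raise ValueError("PAM must match NGG")

    @property
    def is_control(self) -> bool:
        return self.enhancer_id == "NT"


def bin_region(core: GenomicInterval, bin_size: int = BIN_SIZE) -> list[GenomicInterval]:
    """Partition a core region into bins of ``bin_size`` bp.

    A final partial bin of at least 25 bp is kept; a shorter remainder is
    merged into the previous bin (a sub-25 bp core still yields one bin).
    """
    bins = []
    start = core.start
    while start < core.end:
        end = min(start + bin_size, core.end)
        bins.append(GenomicInterval(core.chrom, start, end))
        start = end
    if len(bins) >= 2 and len(bins[-1]) < MIN_REMAINDER:
        last = bins.pop()
        prev = bins.pop()
        bins.append(GenomicInterval(core.chrom, prev.start, last.end))
    return bins


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def enumerate_guides(
    bin_iv: GenomicInterval,
    core: GenomicInterval,
    genome: Genome,
    enhancer_id: str = "",
    core_id: str = "",
    bin_index: int = 0,
) -> list[GuideRecord]:
    """All eligible guide candidates whose cut site falls inside the bin.

    The protospacer must lie fully within the core region; candidates with a
    TTTT stretch, any N, or GC outside [20%, 80%] are excluded. The cut site
    sits between protospacer positions 17 and 18 (3 bp from the PAM).
    """
    seq = genome.sequences[core.chrom]
    out: list[GuideRecord] = []
    # plus strand: protospacer [p, p+20) inside the core, PAM [p+20, p+23)
    # == NGG (PAM may extend past the core), cut between positions 17/18.
    for p in range(core.start, core.end - 19):
        pam = seq[p + 20 : p + 23]
        if len(pam) == 3 and pam[1:] == "GG":
            cut = p + 17
            if bin_iv.start <= cut < bin_iv.end:
                proto = seq[p : p + 20]
                if _eligible(proto):
                    out.append(
                        GuideRecord(
                            "", enhancer_id or "E_unset", core_id, bin_index,
                            proto, pam, "+", cut, 0.0,
                        )
                    )
    # minus strand: CCN at [q-3, q) on the plus strand, protospacer is the
    # reverse complement of [q, q+20) (inside the core); cut 3 bp from PAM.
    for q in range(max(core.start, 3), core.end - 19):
        if seq[q - 3 : q - 1] == "CC":
            cut = q + 3
            if bin_iv.start <= cut < bin_iv.end:
                proto = revcomp(seq[q : q + 20])
                if _eligible(proto):
                    out.append(
                        GuideRecord(
                            "", enhancer_id or "E_unset", core_id, bin_index,
                            proto, revcomp(seq[q - 3 : q]), "-", cut, 0.0,
                        )
                    )
    return out


def _eligible(proto: str) -> bool:
    if "TTTT" in proto or "N" in proto:
        return False
    return 0.2 <= _gc_fraction(proto) <= 0.8


def surrogate_score(protospacer: str) -> float:
    """Deterministic on-target surrogate in [0, 2].

    gc_term: 1.0 for GC in [40%, 60%], 0.5 for [30%, 70%], else 0.25.
    homopolymer_term: 1.0 when no base runs 4+ in a row, else 0.
    """
    gc = _gc_fraction(protospacer)
    if 0.4 <= gc <= 0.6:
        gc_term = 1.0
    elif 0.3 <= gc <= 0.7:
        gc_term = 0.5
    else:
        gc_term = 0.25
    homo = 0.0 if any(b * 4 in protospacer for b in "ACGT") else 1.0
    return gc_term + homo


def score_and_select(
    candidates: list[GuideRecord],
    scorer: Callable[[str], float] = surrogate_score,
) -> GuideRecord | None:
    """Best candidate of one bin: max score, ties to smaller cut site, then +."""
    if not candidates:
        return None
    scored = [
        GuideRecord(
            c.guide_id, c.enhancer_id, c.core_id, c.bin_index,
            c.protospacer, c.pam, c.strand, c.cut_site, scorer(c.protospacer),
        )
        for c in candidates
    ]
    return min(scored, key=lambda c: (-c.score, c.cut_site, 0 if c.strand == "+" else 1))


def design_library(
    cores: list[tuple[str, str, GenomicInterval]],
    genome: Genome,
    bin_size: int = BIN_SIZE,
    scorer: Callable[[str], float] = surrogate_score,
) -> list[GuideRecord]:
    """Tile every (enhancer_id, core_id, interval) core; one best guide per bin.

    Bins without any eligible candidate yield no guide (logged by count in
    the returned records' gaps). Guide ids are assigned in genomic order.
    """
    guides: list[GuideRecord] = []
    for enhancer_id, core_id, core in cores:
        for b_idx, b in enumerate(bin_region(core, bin_size)):
            cands = enumerate_guides(b, core, genome, enhancer_id, core_id, b_idx)
            best = score_and_select(cands, scorer)
            if best is not None:
                guides.append(best)
    return [
        GuideRecord(
            f"sg_{i:05d}", g.enhancer_id, g.core_id, g.bin_index,
            g.protospacer, g.pam, g.strand, g.cut_site, g.score,
        )
        for i, g in enumerate(guides)
    ]


def genome_has_exact_match(genome: Genome, kmer: str) -> bool:
    """Direct string scan of both strands (the slow, obviously-correct path)."""
    rc = revcomp(kmer)
    for seq in genome.sequences.values():
        if kmer in seq or rc in seq:
            return True
    return False


class KmerIndex:
    """Sorted 2-bit-packed index of every 20-mer on the forward strand.

    A k-mer occurs on either genome strand iff its code or its reverse
    complement's code is present. Windows containing non-ACGT bases are
    excluded from the index (they can never exact-match an ACGT guide).
    """

    K = 20

    def __init__(self, genome: Genome):
        if genome.sequences is None:
            raise ValueError("genome has no sequence")
        lut = np.full(256, -1, dtype=np.int64)
        for i, b in enumerate("ACGT"):
            lut[ord(b)] = i
        powers = 4 ** np.arange(self.K - 1, -1, -1, dtype=np.int64)
        chunks = []
        for seq in genome.sequences.values():
            if len(seq) < self.K:
                continue
            av = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
            windows = np.lib.stride_tricks.sliding_window_view(av, self.K)
            codes = windows @ powers
            bad = np.cumsum(np.concatenate([[0], (av < 0).astype(np.int64)]))
            valid = (bad[self.K :] - bad[: -self.K]) == 0
            chunks.append(codes[valid])
        self.codes = np.sort(np.concatenate(chunks)) if chunks else np.empty(0, dtype=np.int64)

    def _encode(self, kmer: str) -> int:
        code = 0
        for b in kmer:
            code = code * 4 + "ACGT".index(b)
        return code

    def __contains__(self, kmer: str) -> bool:
        for probe in (kmer, revcomp(kmer)):
            code = self._encode(probe)
            i = int(np.searchsorted(self.codes, code))
            if i < len(self.codes) and self.codes[i] == code:
                return True
        return False


def make_controls(
    genome: Genome,
    n: int = 1000,
    seed: int = 0,
    min_hamming: int = 1,
    max_draws: int = 10**6,
) -> list[GuideRecord]:
    """Seeded non-targeting controls: random 20-mers absent from the genome.

    Controls have GC in [40%, 60%] and no TTTT stretch, and are rejected if
    an exact match exists on either genome strand. ``min_hamming=2`` enables
    the stricter mode requiring no genomic 20-mer within Hamming distance 1
    (slow; exact-match absence is the default and sufficient on synthetic
    genomes).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    index = KmerIndex(genome)
    out: list[GuideRecord] = []
    seen: set[str] = set()
    draws = 0
    while len(out) < n:
        draws += 1
        if draws > max_draws:
            raise RuntimeError(
                f"exceeded {max_draws} draws generating controls; "
                "genome too small or degenerate"
            )
        kmer = "".join(bases[rng.integers(0, 4, size=20)])
        if kmer in seen or "TTTT" in kmer:
            continue
        if not (0.4 <= _gc_fraction(kmer) <= 0.6):
            continue
        if kmer in index:
            continue
        if min_hamming >= 2 and _has_near_match(genome, kmer):
            continue
        seen.add(kmer)
        out.append(
            GuideRecord(
                f"nt_{len(out):04d}", "NT", "", -1, kmer, "NNN", ".", -1, 0.0
            )
        )
    return out


def _has_near_match(genome: Genome, kmer: str) -> bool:
    for i in range(20):
        for b in "ACGT":
            if b == kmer[i]:
                continue
            variant = kmer[:i] + b + kmer[i + 1 :]
            if genome_has_exact_match(genome, variant):
                return True
    return False


def write_library(guides: list[GuideRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["guide_id", "enhancer_id", "core_id", "bin_index", "protospacer",
             "pam", "strand", "cut_site", "score"]
        )
        for g in guides:
            w.writerow(
                [g.guide_id, g.enhancer_id, g.core_id, g.bin_index,
                 g.protospacer, g.pam, g.strand, g.cut_site, g.score]
            )


def write_protospacer_fasta(guides: list[GuideRecord], path: str) -> None:
    with open(path, "w") as fh:
        for g in guides:
            fh.write(f">{g.guide_id}\n{g.protospacer}\n")
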