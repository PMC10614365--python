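"""Genomic interval data model, interval algebra, and flat-file readers.

All coordinates are 0-based half-open, the BED convention. Conversion to the
1-based inclusive coordinates used in printed reports happens only at report
boundaries (see :func:`to_report_coords`). Chromosome names are compared as
exact strings; an optional normalization flag on the readers strips or adds
the ``chr`` prefix at read time.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "Genome",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_table",
    "merge_intervals",
    "overlap_query",
    "to_report_coords",
    "from_report_coords",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded). ``extra`` carries
    trailing BED columns (name, score, ...) and is excluded from ordering.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    extra: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class Genome:
    """Ordered chromosome names with lengths and optional sequence."""

    lengths: dict[str, int]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.sequences is not None:
            for name, seq in self.sequences.items():
                if name not in self.lengths:
                    raise ValueError(f"sequence for unknown chromosome {name!r}")
                if len(seq) != self.lengths[name]:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared length "
                        f"{self.lengths[name]} for {name!r}"
                    )

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def chrom_rank(self, chrom: str) -> int:
        return self.chroms.index(chrom)

    def fetch(self, interval: GenomicInterval) -> str:
        if self.sequences is None:
            raise ValueError("genome has no sequence")
        return self.sequences[interval.chrom][interval.start : interval.end]

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        seqs = read_fasta(path)
        return cls({n: len(s) for n, s in seqs.items()}, seqs)


class BedParseError(ValueError):
    """Record-level BED parse failure, carrying the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def _open_text(path: str) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _normalize_chrom(chrom: str, chr_prefix: bool | None) -> str:
    if chr_prefix is None:
        return chrom
    has = chrom.startswith("chr")
    if chr_prefix and not has:
        return "chr" + chrom
    if not chr_prefix and has:
        return chrom[3:]
    return chrom


def read_bed(
    path: str, min_fields: int = 3, chr_prefix: bool | None = None
) -> list[GenomicInterval]:
    """Read a BED3+ file into a list of intervals, preserving input order.

    ``track``, ``browser`` and ``#`` comment lines are skipped. Columns beyond
    the sixth are retained in ``extra`` after name/score. ``chr_prefix``
    forces (True) or strips (False) the ``chr`` prefix; None leaves names as
    written.
    """
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields or len(fields) < 3:
                raise BedParseError(
                    line_no, f"expected >= {max(min_fields, 3)} fields, got {len(fields)}"
                )
            chrom = _normalize_chrom(fields[0], chr_prefix)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(line_no, f"non-integer coordinate: {exc}") from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-." else "."
            try:
                out.append(
                    GenomicInterval(chrom, start, end, strand, tuple(fields[3:]))
                )
            except ValueError as exc:
                raise BedParseError(line_no, str(exc)) from None
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    """Write intervals as tab-separated BED, emitting extra columns verbatim."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), *iv.extra]
            fh.write("\t".join(fields) + "\n")


def read_fasta(path: str) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_table(path: str, sep: str = "\t") -> tuple[list[str] | None, list[list[str]]]:
    """Read a delimited table, detecting a header line.

    A header is declared when the first non-comment line contains a field that
    does not parse as a number in a column where later lines do. Returns
    ``(header_or_None, rows)``.
    """

    def _numeric(s: str) -> bool:
        try:
            float(s)
            return True
        except ValueError:
            return False

    rows: list[list[str]] = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split(sep))
    if not rows:
        return None, []
    if len(rows) >= 2:
        first, second = rows[0], rows[1]
        if any(
            not _numeric(a) and _numeric(b) for a, b in zip(first, second)
        ):
            return first, rows[1:]
    return None, rows


def merge_intervals(
    intervals: Sequence[GenomicInterval], min_overlap: int = 1
) -> list[tuple[GenomicInterval, set[int]]]:
    """Union intervals that overlap by at least ``min_overlap`` bp.

    Book-ended intervals (overlap 0) are NOT merged at the default of 1 bp.
    Returns sorted, non-overlapping intervals, each paired with the set of
    contributing input indices.
    """
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end))
    merged: list[tuple[GenomicInterval, set[int]]] = []
    cur: GenomicInterval | None = None
    members: set[int] = set()
    for idx in order:
        iv = intervals[idx]
        if (
            cur is not None
            and iv.chrom == cur.chrom
            and min(cur.end, iv.end) - iv.start >= min_overlap
        ):
            cur = GenomicInterval(cur.chrom, cur.start, max(cur.end, iv.end))
            members.add(idx)
        else:
            if cur is not None:
                merged.append((cur, members))
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
            members = {idx}
    if cur is not None:
        merged.append((cur, members))
    return merged


def overlap_query(
    query: GenomicInterval, subjects: Sequence[GenomicInterval]
) -> list[int]:
    """Indices of subjects sharing >= 1 bp with the query, ascending."""
    return [i for i, s in enumerate(subjects) if query.overlaps(s)]


def to_report_coords(iv: GenomicInterval) -> tuple[str, int, int]:
    """Convert to the 1-based inclusive coordinates used in printed reports."""
    return iv.chrom, iv.start + 1, iv.end


def from_report_coords(chrom: str, start1: int, end1: int) -> GenomicInterval:
    """Build an interval from 1-based inclusive printed coordinates."""
    return GenomicInterval(chrom, start1 - 1, end1)
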