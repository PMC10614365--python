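"""HRR-associated enhancer definition, core regions, and target evaluation.

An H3K27ac peak overlapping any qualifying HRR (a significant SNV/INDEL
hotspot cluster at FDR < 5% or a candidate SV-HRR at >= 10 donors) becomes
an HRR-associated enhancer. Enhancers additionally carrying an H3K4me1 peak
are eligible for screening, and their intervals are narrowed to core
regions by intersection with ATAC peaks (one enhancer may yield several
cores). The functional evaluation compares CRISPR enrichment scores of
presumed enhancer target genes (TSS within 1 Mb of the enhancer) against
targets of HRR-unrelated enhancers with a two-sided Mann-Whitney U test,
per HRR type.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from scipy.stats import mannwhitneyu

from .intervals import GenomicInterval
from .loops import TssRecord

TARGET_WINDOW = 1_000_000  # bp from enhancer edge to gene TSS, inclusive


@dataclass
class Enhancer:
    enhancer_id: str
    interval: GenomicInterval
    hrr_links: list[tuple[str, str]] = field(default_factory=list)  # (hrr_id, type)
    has_h3k4me1: bool = False
    core_regions: list[GenomicInterval] = field(default_factory=list)

    @property
    def hrr_associated(self) -> bool:
        return bool(self.hrr_links)

    @property
    def hrr_types(self) -> tuple[str, ...]:
        return tuple(sorted({t for _, t in self.hrr_links}))


def define_hrr_enhancers(
    hrrs: list[tuple[str, str, GenomicInterval]],
    h3k27ac: list[GenomicInterval],
) -> list[Enhancer]:
    """Classify H3K27ac peaks by HRR overlap; ids follow genomic order.

    ``hrrs`` holds (hrr_id, hrr_type, interval) for every qualifying HRR of
    any type. Every peak becomes an Enhancer; those overlapping >= 1 bp of
    any HRR are HRR-associated, recording all overlapping HRRs.
    """
    peaks = sorted(h3k27ac, key=lambda p: (p.chrom, p.start, p.end))
    out = []
    for i, peak in enumerate(peaks):
        links = [
            (hid, htype) for hid, htype, hiv in hrrs if peak.overlaps(hiv)
        ]
        out.append(Enhancer(f"E_{i + 1:03d}", peak, links))
    return out


def define_core_regions(
    enhancers: list[Enhancer],
    h3k4me1: list[GenomicInterval],
    atac: list[GenomicInterval],
) -> list[Enhancer]:
    """Mark H3K4me1 eligibility and intersect enhancers with ATAC peaks.

    An enhancer is screen-eligible iff it overlaps an H3K4me1 peak; its
    cores are the (non-empty) intersections of its interval with ATAC
    peaks. Enhancers without ATAC overlap keep no cores and drop out of
    library design. Returns the eligible enhancers that received cores.
    """
    eligible = []
    for enh in enhancers:
        enh.has_h3k4me1 = any(enh.interval.overlaps(p) for p in h3k4me1)
        enh.core_regions = []
        if not enh.has_h3k4me1:
            continue
        for peak in atac:
            if enh.interval.overlaps(peak):
                enh.core_regions.append(
                    GenomicInterval(
                        enh.interval.chrom,
                        max(enh.interval.start, peak.start),
                        min(enh.interval.end, peak.end),
                    )
                )
        enh.core_regions.sort(key=lambda c: c.start)
        if enh.core_regions:
            eligible.append(enh)
    return eligible


@dataclass
class TargetAssignment:
    enhancer_id: str
    gene: str
    distance: int
    group: str  # an HRR type, or "HRR-unrelated"


def assign_presumed_targets(
    enhancers: list[Enhancer],
    tss_records: list[TssRecord],
    window: int = TARGET_WINDOW,
) -> list[TargetAssignment]:
    """Genes with TSS within ``window`` bp of an enhancer edge (inclusive).

    A gene reached by both an HRR-associated and an HRR-unrelated enhancer
    is kept in the HRR-associated group only, to avoid contaminating the
    null group.
    """
    assignments: list[TargetAssignment] = []
    for enh in enhancers:
        for rec in tss_records:
            if rec.chrom != enh.interval.chrom:
                continue
            if enh.interval.start <= rec.tss < enh.interval.end:
                dist = 0
            else:
                dist = min(
                    abs(rec.tss - enh.interval.start),
                    abs(rec.tss - (enh.interval.end - 1)),
                )
            if dist > window:
                continue
            if enh.hrr_associated:
                for t in enh.hrr_types:
                    assignments.append(
                        TargetAssignment(enh.enhancer_id, rec.gene, dist, t)
                    )
            else:
                assignments.append(
                    TargetAssignment(enh.enhancer_id, rec.gene, dist, "HRR-unrelated")
                )
    hrr_genes = {a.gene for a in assignments if a.group != "HRR-unrelated"}
    return [
        a
        for a in assignments
        if a.group != "HRR-unrelated" or a.gene not in hrr_genes
    ]


@dataclass
class EnrichmentComparison:
    hrr_type: str
    u_statistic: float
    p_value: float
    n_hrr: int
    n_unrelated: int


def compare_enrichment_scores(
    assignments: list[TargetAssignment],
    gene_scores: dict[str, float],
) -> list[EnrichmentComparison]:
    """Mann-Whitney U of target-gene CRISPR scores, HRR type vs unrelated.

    Two-sided; exact null for combined n <= 20 without ties, otherwise the
    normal approximation with tie correction (scipy's switching rule,
    forced exact at small n). Errors when either group is empty.
    """
    unrelated = sorted(
        {a.gene for a in assignments if a.group == "HRR-unrelated"}
    )
    null_scores = [gene_scores[g] for g in unrelated if g in gene_scores]
    types = sorted({a.group for a in assignments if a.group != "HRR-unrelated"})
    out = []
    for t in types:
        genes = sorted({a.gene for a in assignments if a.group == t})
        scores = [gene_scores[g] for g in genes if g in gene_scores]
        if not scores:
            raise ValueError(f"no scored genes in HRR group {t!r}")
        if not null_scores:
            raise ValueError("no scored genes in the HRR-unrelated group")
        method = "exact" if len(scores) + len(null_scores) <= 20 else "asymptotic"
        try:
            res = mannwhitneyu(scores, null_scores, alternative="two-sided", method=method)
        except ValueError:  # ties with exact method
            res = mannwhitneyu(scores, null_scores, alternative="two-sided", method="asymptotic")
        out.append(
            EnrichmentComparison(
                t, float(res.statistic), float(res.pvalue), len(scores), len(null_scores)
            )
        )
    return out


def write_enhancer_table(enhancers: list[Enhancer], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["enhancer_id", "chrom", "start", "end", "hrr_associated",
             "hrr_types", "has_h3k4me1", "n_cores", "cores"]
        )
        for e in enhancers:
            w.writerow(
                [
                    e.enhancer_id,
                    e.interval.chrom,
                    e.interval.start,
                    e.interval.end,
                    int(e.hrr_associated),
                    ",".join(e.hrr_types),
                    int(e.has_h3k4me1),
                    len(e.core_regions),
                    ";".join(f"{c.start}-{c.end}" for c in e.core_regions),
                ]
            )
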