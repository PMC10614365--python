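"""Seeded synthetic-cohort generators with planted ground truth.

Every input the pipeline consumes can be generated here: per-donor SV call
sets from two emulated callers with planted recurrent regions over a
Poisson background, covariate-modulated somatic SNVs with planted hotspots
and a dominant UV-like substitution signature, peak tracks (H3K27ac,
H3K4me1, ATAC) covering the planted regions, enhancer-promoter loops, and
negative-binomial CRISPRi screen counts with planted enriched enhancers.

Default parameters mirror the emulated study's conditions: 297 donors, two
SV callers with 0.9 per-call sensitivity and <= 100 bp breakpoint jitter,
10 kb-scale recurrent regions, a melanoma-like point-mutation burden of
about 10 mutations per Mb per donor dominated by a UV-like C>T profile,
50 kb piecewise-constant covariate tiles (so expected counts integrate in
closed form), a 500x screen depth with two replicates at day 0 and day 21,
and 1000 non-targeting control guides. All draws are deterministic under
(seed, config); sub-streams are derived per component so generators can be
called independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .guides import GuideRecord
from .intervals import Genome, GenomicInterval
from .loops import Loop, TssRecord
from .mutsig import (
    SBS96_CATEGORIES,
    Signature,
    platinum_like_profile,
    revcomp,
    uv_like_profile,
)
from .screen import CountMatrix
from .snv_hrr import CovariateTracks, SnvCall
from .sv_hrr import SvCall

import pandas as pd

MAX_BACKGROUND_SV_LEN = 5_000_000  # some draws exceed the 1 Mb filter on purpose
CALLER_NAMES = ("manta_like", "gridss_like")
CALLER_SENSITIVITY = 0.9
BREAKPOINT_JITTER = 100  # bp, per caller, planted SVs


@dataclass(frozen=True)
class PlantedHrr:
    interval: GenomicInterval
    sv_type: str
    n_carriers: int


@dataclass(frozen=True)
class PlantedHotspot:
    interval: GenomicInterval
    fold: float


@dataclass
class ScreenConfig:
    n_enhancers: int = 200
    guides_per_enhancer: int = 10
    n_controls: int = 1000
    depth: float = 500.0
    dispersion: float = 0.05  # NB: var = m + dispersion * m^2
    n_replicates: int = 2
    planted_effects: dict[str, float] = field(default_factory=dict)  # log2 FC


@dataclass
class SimConfig:
    """Full study-condition specification for the synthetic cohort."""

    seed: int = 0
    n_donors: int = 297
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    sv_background_rate: float = 0.5  # SVs per donor per Mb per type
    planted_hrrs: list[PlantedHrr] = field(default_factory=list)
    snv_rate: float = 1e-5  # per bp per donor (~10 mutations/Mb, melanoma-like)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"accessibility": 0.5, "rep_timing": 0.3}
    )
    state_effects: dict[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 0.3, "C": -0.2}
    )
    planted_hotspots: list[PlantedHotspot] = field(default_factory=list)
    signature_mix: dict[str, float] = field(
        default_factory=lambda: {"UV_like": 0.8, "Platinum_like": 0.2}
    )
    tile_size: int = 50_000
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    def __post_init__(self) -> None:
        if self.signature_mix:
            total = sum(self.signature_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("signature_mix proportions must sum to 1")
        if self.sv_background_rate < 0 or self.snv_rate < 0:
            raise ValueError("rates must be >= 0")
        for p in self.planted_hrrs:
            self._check_inside(p.interval)
            if p.n_carriers > self.n_donors:
                raise ValueError(
                    f"planted HRR carriers ({p.n_carriers}) exceed donors ({self.n_donors})"
                )
        for h in self.planted_hotspots:
            self._check_inside(h.interval)

    def _check_inside(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_lengths or iv.end > self.chrom_lengths[iv.chrom]:
            raise ValueError(f"planted interval {iv} outside genome")

    def donors(self) -> list[str]:
        return [f"D{i:04d}" for i in range(self.n_donors)]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, abs(hash_stream(stream)) % 2**31])
        )


def hash_stream(name: str) -> int:
    # stable across processes (hash() is salted); small and cheap
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % 2**31
    return h


@dataclass
class GroundTruth:
    planted_hrrs: list[PlantedHrr] = field(default_factory=list)
    planted_hotspots: list[PlantedHotspot] = field(default_factory=list)
    enriched_enhancers: dict[str, float] = field(default_factory=dict)
    signature_labels: list[str] = field(default_factory=list)
    decoy_loops: list[int] = field(default_factory=list)  # indices of sub/super-threshold loops
    enhancer_genes: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "planted_hrrs": [
                {
                    "chrom": p.interval.chrom,
                    "start": p.interval.start,
                    "end": p.interval.end,
                    "sv_type": p.sv_type,
                    "n_carriers": p.n_carriers,
                }
                for p in self.planted_hrrs
            ],
            "planted_hotspots": [
                {
                    "chrom": h.interval.chrom,
                    "start": h.interval.start,
                    "end": h.interval.end,
                    "fold": h.fold,
                }
                for h in self.planted_hotspots
            ],
            "enriched_enhancers": self.enriched_enhancers,
            "signature_labels": self.signature_labels,
            "decoy_loops": self.decoy_loops,
            "enhancer_genes": self.enhancer_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# genome


def gen_genome(cfg: SimConfig, with_sequence: bool = True) -> Genome:
    """Random A/C/G/T genome with tile-scale GC variation (for the GC covariate)."""
    if not with_sequence:
        return Genome(dict(cfg.chrom_lengths))
    rng = cfg.rng("genome")
    seqs = {}
    bases = np.array(list("ACGT"))
    for chrom, length in cfg.chrom_lengths.items():
        parts = []
        pos = 0
        while pos < length:
            n = min(cfg.tile_size, length - pos)
            gc = rng.uniform(0.3, 0.6)
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            parts.append("".join(bases[rng.choice(4, size=n, p=p)]))
            pos += n
        seqs[chrom] = "".join(parts)
    return Genome(dict(cfg.chrom_lengths), seqs)


# ---------------------------------------------------------------------------
# structural variants


def _random_sv_length(rng: np.random.Generator) -> int:
    # log-uniform in [50 bp, 1 Mb]; 10% of draws in (1 Mb, 5 Mb] so the
    # downstream length filter is exercised
    if rng.random() < 0.1:
        return int(np.exp(rng.uniform(np.log(1_000_001), np.log(MAX_BACKGROUND_SV_LEN))))
    return int(np.exp(rng.uniform(np.log(50), np.log(1_000_000))))


def gen_sv_callsets(cfg: SimConfig) -> tuple[list[SvCall], GroundTruth]:
    """Per-donor, per-caller SV call sets with planted recurrent regions.

    Background SVs arise per donor per type as Poisson(rate x Mb) with
    log-uniform lengths; each caller reports a background SV independently
    with sensitivity 0.9. Planted SVs (one per carrier, overlapping the
    planted interval) are reported by both callers with breakpoints
    jittered by at most 100 bp.
    """
    rng = cfg.rng("sv")
    donors = cfg.donors()
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    genome_mb = lengths.sum() / 1e6
    calls: list[SvCall] = []
    for donor in donors:
        for sv_type in ("DEL", "DUP", "INV", "TRA"):
            if sv_type == "TRA" and len(chroms) < 2:
                continue
            n = rng.poisson(cfg.sv_background_rate * genome_mb)
            for _ in range(n):
                if sv_type == "TRA":
                    c1, c2 = rng.choice(len(chroms), size=2, replace=False)
                    pos1 = int(rng.integers(0, cfg.chrom_lengths[chroms[c1]]))
                    pos2 = int(rng.integers(0, cfg.chrom_lengths[chroms[c2]]))
                    proto = ("TRA", chroms[c1], pos1, chroms[c2], pos2)
                else:
                    ci = rng.choice(len(chroms), p=chrom_p)
                    length = _random_sv_length(rng)
                    clen = cfg.chrom_lengths[chroms[ci]]
                    length = min(length, clen - 1)
                    pos1 = int(rng.integers(0, clen - length))
                    proto = (sv_type, chroms[ci], pos1, chroms[ci], pos1 + length)
                for caller in CALLER_NAMES:
                    if rng.random() < CALLER_SENSITIVITY:
                        calls.append(SvCall(donor, caller, *proto))
    # planted recurrent regions: both callers, jittered breakpoints
    for planted in cfg.planted_hrrs:
        iv = planted.interval
        carriers = rng.choice(cfg.n_donors, size=planted.n_carriers, replace=False)
        for d_idx in sorted(carriers):
            donor = donors[d_idx]
            center = (iv.start + iv.end) // 2
            if planted.sv_type in ("DEL", "DUP"):
                # fragment spans the interval center with margin > jitter
                half = max(len(iv) // 2 + 500, 1_000)
                base1 = max(0, center - half)
                base2 = min(cfg.chrom_lengths[iv.chrom], center + half)
                for caller in CALLER_NAMES:
                    j1 = int(rng.integers(-BREAKPOINT_JITTER, BREAKPOINT_JITTER + 1))
                    j2 = int(rng.integers(-BREAKPOINT_JITTER, BREAKPOINT_JITTER + 1))
                    calls.append(
                        SvCall(
                            donor, caller, planted.sv_type,
                            iv.chrom, max(0, base1 + j1),
                            iv.chrom, min(cfg.chrom_lengths[iv.chrom], base2 + j2),
                        )
                    )
            else:
                # breakend inside the interval, kept inside after jitter
                lo = iv.start + BREAKPOINT_JITTER
                hi = iv.end - BREAKPOINT_JITTER
                if lo >= hi:
                    lo, hi = iv.start, iv.end
                base = int(rng.integers(lo, hi))
                if planted.sv_type == "INV":
                    mate = min(cfg.chrom_lengths[iv.chrom] - 1, base + 50_000)
                    proto_mate = (iv.chrom, mate)
                else:
                    other = next(c for c in chroms if c != iv.chrom)
                    proto_mate = (other, int(rng.integers(0, cfg.chrom_lengths[other])))
                for caller in CALLER_NAMES:
                    j = int(rng.integers(-BREAKPOINT_JITTER, BREAKPOINT_JITTER + 1))
                    pos = int(np.clip(base + j, iv.start, iv.end - 1))
                    calls.append(
                        SvCall(
                            donor, caller, planted.sv_type,
                            iv.chrom, pos, proto_mate[0], proto_mate[1],
                        )
                    )
    truth = GroundTruth(planted_hrrs=list(cfg.planted_hrrs))
    return calls, truth


# ---------------------------------------------------------------------------
# SNVs


_PROFILES = {
    "UV_like": uv_like_profile,
    "Platinum_like": platinum_like_profile,
}


def resolve_signature_mix(cfg: SimConfig) -> Signature:
    """Combine named or custom profiles into one sampling profile."""
    combined = np.zeros(96)
    for name, weight in cfg.signature_mix.items():
        if name in _PROFILES:
            combined += weight * _PROFILES[name]().weights
        else:
            raise ValueError(f"unknown signature profile {name!r}")
    return Signature(combined, label="mix")


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


def _chrom_context_codes(seq: str) -> np.ndarray:
    """Per-position pyrimidine-normalized context code (0..31), -1 at edges.

    code = 16 x (center is T) + 4 x five-prime + three-prime, where flanks
    are indexed A/C/G/T after reverse-complementing purine-center sites.
    """
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(len(a), -1, dtype=np.int8)
    lut = np.full(256, -1, dtype=np.int8)
    for b, v in _BASE_CODE.items():
        lut[ord(b)] = v
    av = lut[a]
    center = av[1:-1]
    left = av[:-2]
    right = av[2:]
    is_pyr = (center == 1) | (center == 3)
    is_pur = (center == 0) | (center == 2)
    out = np.full(len(center), -1, dtype=np.int16)
    # pyrimidine center: keep orientation
    c_t = (center == 3).astype(np.int16)
    out[is_pyr] = (16 * c_t + 4 * left + right)[is_pyr]
    # purine center: reverse complement (G->C code 0, A->T code 16)
    c_t_pur = (center == 0).astype(np.int16)
    out[is_pur] = (16 * c_t_pur + 4 * (3 - right) + (3 - left))[is_pur]
    full = np.full(len(a), -1, dtype=np.int16)
    full[1:-1] = out
    return full


def gen_snv_callsets(
    cfg: SimConfig, genome: Genome | None = None
) -> tuple[list[SnvCall], CovariateTracks, GroundTruth]:
    """Covariate-modulated somatic SNVs with planted hotspots.

    Covariates (accessibility, replication timing, categorical chromatin
    state) are constant over ``tile_size`` tiles; the per-bp intensity is
    snv_rate x exp(sum effects x covariates), multiplied by the hotspot
    fold inside planted hotspots. Substitution types follow the configured
    signature mix conditioned on each site's reference trinucleotide.
    """
    if genome is None:
        genome = gen_genome(cfg, with_sequence=True)
    if genome.sequences is None:
        raise ValueError("genome sequence required (trinucleotide contexts)")
    rng = cfg.rng("snv")
    profile = resolve_signature_mix(cfg).weights
    if profile.sum() <= 0:
        raise ValueError("signature mix carries no mass")
    state_labels = tuple(sorted(cfg.state_effects))
    tracks = _gen_covariate_tracks(cfg, rng, state_labels)
    codes = {c: _chrom_context_codes(s) for c, s in genome.sequences.items()}
    calls: list[SnvCall] = []
    for chrom, length in cfg.chrom_lengths.items():
        seq = genome.sequences[chrom]
        n_tiles = (length + cfg.tile_size - 1) // cfg.tile_size
        for t in range(n_tiles):
            t_start = t * cfg.tile_size
            t_end = min(t_start + cfg.tile_size, length)
            lam_bp = cfg.snv_rate * _tile_multiplier(cfg, tracks, chrom, t, state_labels)
            expected = lam_bp * (t_end - t_start) * cfg.n_donors
            calls.extend(
                _draw_mutations(
                    cfg, rng, seq, codes[chrom], chrom, t_start, t_end,
                    expected, profile,
                )
            )
    # hotspots: extra intensity (fold - 1) x background inside the interval
    for hot in cfg.planted_hotspots:
        chrom = hot.interval.chrom
        seq = genome.sequences[chrom]
        start, end = hot.interval.start, hot.interval.end
        t0 = start // cfg.tile_size
        t1 = (end - 1) // cfg.tile_size
        for t in range(t0, t1 + 1):
            lo = max(start, t * cfg.tile_size)
            hi = min(end, (t + 1) * cfg.tile_size)
            lam_bp = cfg.snv_rate * _tile_multiplier(cfg, tracks, chrom, t, state_labels)
            expected = lam_bp * (hi - lo) * cfg.n_donors * (hot.fold - 1.0)
            calls.extend(
                _draw_mutations(
                    cfg, rng, seq, codes[chrom], chrom, lo, hi, expected, profile
                )
            )
    truth = GroundTruth(
        planted_hotspots=list(cfg.planted_hotspots),
        signature_labels=sorted(cfg.signature_mix),
    )
    return calls, tracks, truth


def _gen_covariate_tracks(
    cfg: SimConfig, rng: np.random.Generator, state_labels: tuple[str, ...]
) -> CovariateTracks:
    numeric = {"accessibility": {}, "rep_timing": {}}
    state: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chrom_lengths.items():
        n_tiles = (length + cfg.tile_size - 1) // cfg.tile_size
        numeric["accessibility"][chrom] = rng.normal(0, 1, n_tiles)
        numeric["rep_timing"][chrom] = rng.normal(0, 1, n_tiles)
        state[chrom] = np.array(state_labels)[rng.integers(0, len(state_labels), n_tiles)]
    return CovariateTracks(cfg.tile_size, numeric, state, state_labels)


def _tile_multiplier(
    cfg: SimConfig,
    tracks: CovariateTracks,
    chrom: str,
    tile: int,
    state_labels: tuple[str, ...],
) -> float:
    log_m = 0.0
    for name, effect in cfg.covariate_effects.items():
        log_m += effect * tracks.numeric[name][chrom][tile]
    if tracks.state is not None:
        log_m += cfg.state_effects[tracks.state[chrom][tile]]
    return float(np.exp(log_m))


_SUB_ALTS = {"C": ("A", "G", "T"), "T": ("A", "C", "G")}


def _draw_mutations(
    cfg: SimConfig,
    rng: np.random.Generator,
    seq: str,
    codes: np.ndarray,
    chrom: str,
    start: int,
    end: int,
    expected: float,
    profile: np.ndarray,
) -> list[SnvCall]:
    """Poisson(expected) mutation draws over [start, end).

    Each mutation's SBS-96 category is drawn from the signature mix
    (restricted to categories whose context occurs in the region), then
    placed uniformly among the matching positions, so the marginal category
    distribution follows the mix.
    """
    out: list[SnvCall] = []
    n = rng.poisson(expected)
    if n == 0:
        return out
    lo = max(start, 1)
    hi = min(end, len(seq) - 1)
    if hi <= lo:
        return out
    region_codes = codes[lo:hi]
    # category c: substitution class c//16, context code (c//48)*16 + c%16
    cat = np.arange(96)
    cat_ctx = (cat // 48) * 16 + cat % 16
    present = np.isin(cat_ctx, np.unique(region_codes))
    weights = np.where(present, profile, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            "signature profile incompatible with reference base composition"
        )
    weights = weights / total
    donors = cfg.donors()
    drawn = rng.choice(96, size=n, p=weights)
    pos_cache: dict[int, np.ndarray] = {}
    for c in drawn:
        ctx_code = int(cat_ctx[c])
        if ctx_code not in pos_cache:
            pos_cache[ctx_code] = np.flatnonzero(region_codes == ctx_code) + lo
        pos = int(pos_cache[ctx_code][rng.integers(0, len(pos_cache[ctx_code]))])
        ref = seq[pos]
        sub_class = int(c) // 16  # 0..2 C ref, 3..5 T ref on pyrimidine strand
        pyr_center = "C" if sub_class < 3 else "T"
        pyr_alt = _SUB_ALTS[pyr_center][sub_class % 3]
        alt = pyr_alt if ref in "CT" else revcomp(pyr_alt)
        donor = donors[int(rng.integers(0, cfg.n_donors))]
        out.append(SnvCall(donor, chrom, pos, ref, alt))
    return out


def gen_cluster_counts(
    n_clusters: int,
    seed: int,
    beta: tuple[float, float] = (-7.0, 1.0),
    theta: float = 10.0,
    n_hotspots: int = 0,
    hotspot_fold: float = 5.0,
    hotspot_length: int = 1000,
    hotspot_x: float | None = 0.0,
    length_range: tuple[int, int] = (100, 2000),
) -> tuple[list, np.ndarray]:
    """Cluster-level Gamma-Poisson draws for calibration and power studies.

    Each cluster gets one standard-normal covariate x and a log-uniform
    length L; counts are NB(mu, theta) with log mu = log L + b0 + b1 x.
    The last ``n_hotspots`` clusters are hotspots: fixed length, mean
    multiplied by ``hotspot_fold`` relative to the covariate-matched
    background. ``hotspot_x`` pins hotspot covariates at a reference value
    (default 0, the covariate mean) so the fold is the only systematic
    difference; None draws them from the same N(0,1) as the background.
    Returns (clusters, is_hotspot mask).
    """
    from .snv_hrr import MutCluster

    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n_clusters)
    L = np.exp(
        rng.uniform(np.log(length_range[0]), np.log(length_range[1]), n_clusters)
    ).astype(int)
    is_hot = np.zeros(n_clusters, dtype=bool)
    if n_hotspots:
        is_hot[-n_hotspots:] = True
        L[is_hot] = hotspot_length
        if hotspot_x is not None:
            x[is_hot] = hotspot_x
    mu = L * np.exp(beta[0] + beta[1] * x)
    mu[is_hot] *= hotspot_fold
    y = rng.negative_binomial(theta, theta / (theta + mu))
    clusters = [
        MutCluster(
            GenomicInterval("sim", i * 10_000, i * 10_000 + int(li)),
            [], int(yi), {"x": float(xi)},
        )
        for i, (li, yi, xi) in enumerate(zip(L, y, x))
    ]
    return clusters, is_hot


# ---------------------------------------------------------------------------
# peaks, TSS, loops


@dataclass
class TracksAndLoops:
    h3k27ac: list[GenomicInterval]
    h3k4me1: list[GenomicInterval]
    atac: list[GenomicInterval]
    tss: list[TssRecord]
    loops: list[Loop]
    truth: GroundTruth


def gen_tracks_and_loops(
    cfg: SimConfig,
    planted_intervals: list[GenomicInterval] | None = None,
    n_decoy_peaks: int = 30,
    n_decoy_genes: int = 20,
    anchor_size: int = 5_000,
) -> TracksAndLoops:
    """Peak tracks, TSS table, and loops consistent with the planted truth.

    Every planted interval (the planted SV-HRRs and hotspots by default) is
    covered by an H3K27ac and an H3K4me1 peak and contains an ATAC peak of
    150-1000 bp. Each planted enhancer loops to a dedicated gene TSS at an
    anchor-midpoint distance in [20 kb, 2 Mb]; decoy loops below 20 kb and
    above 2 Mb are emitted and flagged in the ground truth.
    """
    rng = cfg.rng("tracks")
    if planted_intervals is None:
        planted_intervals = [p.interval for p in cfg.planted_hrrs] + [
            h.interval for h in cfg.planted_hotspots
        ]
    h3k27ac, h3k4me1, atac = [], [], []
    tss: list[TssRecord] = []
    loops: list[Loop] = []
    truth = GroundTruth(planted_hrrs=list(cfg.planted_hrrs))
    occupied: list[GenomicInterval] = []
    for i, iv in enumerate(planted_intervals):
        clen = cfg.chrom_lengths[iv.chrom]
        pad27 = int(rng.integers(200, 800))
        pad4 = int(rng.integers(500, 1200))
        h3k27ac.append(
            GenomicInterval(iv.chrom, max(0, iv.start - pad27), min(clen, iv.end + pad27))
        )
        h3k4me1.append(
            GenomicInterval(iv.chrom, max(0, iv.start - pad4), min(clen, iv.end + pad4))
        )
        alen = int(rng.integers(150, min(1001, max(151, len(iv)))))
        a_start = iv.start + max(0, (len(iv) - alen) // 2)
        atac.append(GenomicInterval(iv.chrom, a_start, min(a_start + alen, iv.end)))
        occupied.append(h3k27ac[-1])
        # dedicated gene at a loopable distance
        center = (iv.start + iv.end) // 2
        for _ in range(100):
            dist = int(rng.integers(20_000, 2_000_001))
            sign = 1 if rng.random() < 0.5 else -1
            t_pos = center + sign * dist
            if 1000 < t_pos < clen - 1000:
                break
        strand = "+" if rng.random() < 0.5 else "-"
        gene = f"G{i:03d}"
        tss.append(TssRecord(gene, iv.chrom, t_pos, strand))
        truth.enhancer_genes[gene] = f"planted_{i}"
        loops.append(
            Loop(
                GenomicInterval(iv.chrom, max(0, center - anchor_size // 2), min(clen, center + anchor_size // 2)),
                GenomicInterval(iv.chrom, max(0, t_pos - anchor_size // 2), min(clen, t_pos + anchor_size // 2)),
                q=0.001,
            )
        )
    # decoy peaks away from planted regions
    chroms = list(cfg.chrom_lengths)
    placed = 0
    attempts = 0
    while placed < n_decoy_peaks and attempts < 10_000:
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = cfg.chrom_lengths[chrom]
        width = int(rng.integers(500, 3000))
        start = int(rng.integers(0, clen - width))
        cand = GenomicInterval(chrom, start, start + width)
        if any(cand.overlap_len(o) > 0 or _near(cand, o, 10_000) for o in occupied):
            continue
        h3k27ac.append(cand)
        occupied.append(cand)
        placed += 1
    # decoy genes
    for j in range(n_decoy_genes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = cfg.chrom_lengths[chrom]
        tss.append(
            TssRecord(
                f"DG{j:03d}", chrom, int(rng.integers(1000, clen - 1000)),
                "+" if rng.random() < 0.5 else "-",
            )
        )
    # decoy loops: one below the 20 kb bound, one above 2 Mb (if it fits)
    if planted_intervals:
        iv = planted_intervals[0]
        clen = cfg.chrom_lengths[iv.chrom]
        center = (iv.start + iv.end) // 2
        short_target = min(clen - anchor_size, center + 10_000)
        loops.append(
            Loop(
                GenomicInterval(iv.chrom, max(0, center - anchor_size // 2), center + anchor_size // 2),
                GenomicInterval(iv.chrom, max(0, short_target - anchor_size // 2), short_target + anchor_size // 2),
                q=0.001,
            )
        )
        truth.decoy_loops.append(len(loops) - 1)
        far = center + 2_500_000
        if far + anchor_size < clen:
            loops.append(
                Loop(
                    GenomicInterval(iv.chrom, center - anchor_size // 2, center + anchor_size // 2),
                    GenomicInterval(iv.chrom, far - anchor_size // 2, far + anchor_size // 2),
                    q=0.001,
                )
            )
            truth.decoy_loops.append(len(loops) - 1)
    return TracksAndLoops(h3k27ac, h3k4me1, atac, tss, loops, truth)


def _near(a: GenomicInterval, b: GenomicInterval, margin: int) -> bool:
    return a.chrom == b.chrom and a.start < b.end + margin and b.start < a.end + margin


# ---------------------------------------------------------------------------
# screen counts


def toy_library(
    cfg: SimConfig, seed_offset: int = 0
) -> list[GuideRecord]:
    """A membership-only guide library matching the screen config.

    Protospacers are random 20-mers; the library exists to exercise the
    screen statistics, not the design rules.
    """
    rng = cfg.rng(f"toylib{seed_offset}")
    bases = np.array(list("ACGT"))
    guides = []
    gid = 0
    for e in range(cfg.screen.n_enhancers):
        for _ in range(cfg.screen.guides_per_enhancer):
            proto = "".join(bases[rng.integers(0, 4, 20)])
            guides.append(
                GuideRecord(
                    f"sg_{gid:05d}", f"E_{e + 1:03d}", f"core_{e}", 0,
                    proto, "AGG", "+", 0, 1.0,
                )
            )
            gid += 1
    for c in range(cfg.screen.n_controls):
        proto = "".join(bases[rng.integers(0, 4, 20)])
        guides.append(
            GuideRecord(f"nt_{c:04d}", "NT", "", -1, proto, "NNN", ".", -1, 0.0)
        )
    return guides


def gen_screen_counts(
    cfg: SimConfig, library: list[GuideRecord]
) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial screen counts with planted enhancer effects.

    Day-0 counts are NB(depth x guide abundance, dispersion); day-21 means
    are multiplied by 2^effect for guides of planted enhancers (2^0 for
    everything else, controls included). Two replicates per timepoint.
    """
    if not any(g.is_control for g in library):
        raise ValueError("library must include non-targeting controls")
    rng = cfg.rng("screen")
    sc = cfg.screen
    n = len(library)
    abundance = np.exp(rng.normal(0, 0.3, n))
    abundance /= abundance.mean()
    mean0 = sc.depth * abundance
    effects = np.array(
        [
            sc.planted_effects.get(g.enhancer_id, 0.0) if not g.is_control else 0.0
            for g in library
        ]
    )
    mean21 = mean0 * np.power(2.0, effects)
    samples = {}
    for rep in range(1, sc.n_replicates + 1):
        samples[f"day0_r{rep}"] = _nb_draw(rng, mean0, sc.dispersion)
        samples[f"day21_r{rep}"] = _nb_draw(rng, mean21, sc.dispersion)
    counts = pd.DataFrame(samples, index=[g.guide_id for g in library])
    meta = pd.DataFrame(
        [
            {"sample": s, "timepoint": s.split("_")[0], "replicate": int(s.split("_r")[1])}
            for s in counts.columns
        ]
    ).set_index("sample")
    membership = {
        g.guide_id: (None if g.is_control else g.enhancer_id) for g in library
    }
    truth = GroundTruth(enriched_enhancers=dict(sc.planted_effects))
    return CountMatrix(counts, meta, membership), truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# file writers


def write_sv_bedpe(calls: list[SvCall], path: str) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            fh.write(
                "\t".join(
                    [
                        c.chrom1, str(c.pos1), str(c.pos1 + 1),
                        c.chrom2, str(c.pos2), str(c.pos2 + 1),
                        f"sv_{i}", c.donor_id, c.caller, c.sv_type,
                    ]
                )
                + "\n"
            )


def read_sv_bedpe(path: str) -> list[SvCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(
                SvCall(f[7], f[8], f[9], f[0], int(f[1]), f[3], int(f[4]))
            )
    return calls


def write_snv_vcf(calls: list[SnvCall], path: str) -> None:
    """Minimal per-cohort VCF (CHROM POS ID REF ALT), donor in the ID field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t{c.donor_id}\t{c.ref}\t{c.alt}\t.\t.\t.\n"
            )


def read_snv_vcf(path: str) -> list[SnvCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            calls.append(SnvCall(f[2], f[0], int(f[1]) - 1, f[3], f[4]))
    return calls


def write_loops_bedpe(loops: list[Loop], path: str) -> None:
    with open(path, "w") as fh:
        for i, lp in enumerate(loops):
            fh.write(
                "\t".join(
                    [
                        lp.anchor1.chrom, str(lp.anchor1.start), str(lp.anchor1.end),
                        lp.anchor2.chrom, str(lp.anchor2.start), str(lp.anchor2.end),
                        f"loop_{i}", f"{lp.q:.6g}",
                    ]
                )
                + "\n"
            )


def write_tss_table(tss: list[TssRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\ttss\tstrand\n")
        for r in tss:
            fh.write(f"{r.gene}\t{r.chrom}\t{r.tss}\t{r.strand}\n")


def write_counts_tsv(cm: CountMatrix, path: str) -> None:
    df = cm.counts.copy()
    df.insert(
        0, "enhancer_id",
        [cm.membership[g] if cm.membership[g] else "NT" for g in df.index],
    )
    df.to_csv(path, sep="\t", index_label="guide_id")


def config_to_yaml(cfg: SimConfig, path: str) -> None:
    payload = {
        "seed": cfg.seed,
        "n_donors": cfg.n_donors,
        "chrom_lengths": dict(cfg.chrom_lengths),
        "sv_background_rate": cfg.sv_background_rate,
        "snv_rate": cfg.snv_rate,
        "tile_size": cfg.tile_size,
        "covariate_effects": dict(cfg.covariate_effects),
        "state_effects": dict(cfg.state_effects),
        "signature_mix": dict(cfg.signature_mix),
        "planted_hrrs": [
            [p.interval.chrom, p.interval.start, p.interval.end, p.sv_type, p.n_carriers]
            for p in cfg.planted_hrrs
        ],
        "planted_hotspots": [
            [h.interval.chrom, h.interval.start, h.interval.end, h.fold]
            for h in cfg.planted_hotspots
        ],
        "screen": {
            "n_enhancers": cfg.screen.n_enhancers,
            "guides_per_enhancer": cfg.screen.guides_per_enhancer,
            "n_controls": cfg.screen.n_controls,
            "depth": cfg.screen.depth,
            "dispersion": cfg.screen.dispersion,
            "n_replicates": cfg.screen.n_replicates,
            "planted_effects": dict(cfg.screen.planted_effects),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path: str) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    screen = d.pop("screen", {})
    hrrs = [
        PlantedHrr(GenomicInterval(c, s, e), t, n)
        for c, s, e, t, n in d.pop("planted_hrrs", [])
    ]
    hots = [
        PlantedHotspot(GenomicInterval(c, s, e), f)
        for c, s, e, f in d.pop("planted_hotspots", [])
    ]
    return SimConfig(
        planted_hrrs=hrrs,
        planted_hotspots=hots,
        screen=ScreenConfig(**screen),
        **d,
    )
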