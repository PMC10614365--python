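"""End-to-end orchestration of the recurrent-region discovery pipeline.

``run_all`` wires the stages together on a synthetic cohort: simulate ->
SV-HRR calling -> SNV/INDEL hotspot testing -> enhancer annotation ->
sgRNA library design -> screen simulation and RRA -> loop target
assignment -> mutational signatures. Every stage writes its table under
the output directory and contributes record counts to a run manifest;
reruns with the same config and seed reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import enhancers as enh_mod
from . import guides as guides_mod
from . import loops as loops_mod
from . import mutsig as mutsig_mod
from . import screen as screen_mod
from . import simulate as sim
from . import snv_hrr, sv_hrr
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    out_dir: str = "pipeline_out"
    seed_min_donors: int = 4
    candidate_min_donors: int = 10
    cluster_gap: int = 200
    fdr: float = 0.05
    bin_size: int = 100
    n_controls: int = 1000
    rra_alpha: float = 0.25
    n_perm: int = 1000
    n_screen_hits: int = 5
    screen_effect: float = 1.5  # log2 FC planted on screened enhancers
    mutsig_k: int = 2
    mutsig_restarts: int = 5


def demo_config(seed: int = 7) -> PipelineConfig:
    """A compact, fully planted demonstration cohort.

    The SV background density (0.02 SV/Mb/donor/type) matches the low
    structural-variant burden of real tumor genomes; the point-mutation
    rate (1.5e-5/bp/donor, ~15/Mb) is melanoma-like so that 200 bp-linkage
    clusters carry multiple mutations; hotspots are planted at 10-fold.
    """
    hrrs = [
        sim.PlantedHrr(GenomicInterval("chr1", 600_000 + i * 900_000, 610_000 + i * 900_000), "DEL", 12)
        for i in range(6)
    ] + [
        sim.PlantedHrr(GenomicInterval("chr1", 300_000, 310_000), "DUP", 12),
        sim.PlantedHrr(GenomicInterval("chr1", 6_300_000, 6_310_000), "DUP", 14),
    ]
    hotspots = [
        sim.PlantedHotspot(GenomicInterval("chr2", 1_500_000 + i * 1_600_000, 1_501_000 + i * 1_600_000), 10.0)
        for i in range(4)
    ]
    cfg = sim.SimConfig(
        seed=seed,
        n_donors=120,
        chrom_lengths={"chr1": 8_000_000, "chr2": 8_000_000},
        sv_background_rate=0.02,
        snv_rate=1.5e-5,
        planted_hrrs=hrrs,
        planted_hotspots=hotspots,
        screen=sim.ScreenConfig(n_enhancers=0),  # filled from annotation
    )
    return PipelineConfig(sim=cfg, n_screen_hits=3)


def run_all(cfg: PipelineConfig) -> dict:
    """Execute all stages, returning (and writing) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.sim.seed,
        "parameters": {
            "seed_min_donors": cfg.seed_min_donors,
            "candidate_min_donors": cfg.candidate_min_donors,
            "cluster_gap": cfg.cluster_gap,
            "fdr": cfg.fdr,
            "bin_size": cfg.bin_size,
            "n_controls": cfg.n_controls,
            "rra_alpha": cfg.rra_alpha,
            "n_perm": cfg.n_perm,
        },
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                counts = fn()
            except Exception as exc:  # halt, name the stage, keep prior output
                _write_manifest(manifest, out)
                raise StageError(name, exc) from exc
            manifest["stages"].append(
                {"name": name, "records": counts, "seconds": round(time.time() - t0, 3)}
            )

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        genome = sim.gen_genome(cfg.sim)
        sv_calls, sv_truth = sim.gen_sv_callsets(cfg.sim)
        snv_calls, tracks, snv_truth = sim.gen_snv_callsets(cfg.sim, genome)
        tl = sim.gen_tracks_and_loops(cfg.sim)
        state.update(
            genome=genome, sv_calls=sv_calls, snv_calls=snv_calls,
            tracks=tracks, tl=tl,
        )
        sim.write_sv_bedpe(sv_calls, str(out / "sv_calls.bedpe"))
        sim.write_snv_vcf(snv_calls, str(out / "snv_calls.vcf"))
        sim.write_loops_bedpe(tl.loops, str(out / "loops.bedpe"))
        sim.write_tss_table(tl.tss, str(out / "tss.tsv"))
        sim.config_to_yaml(cfg.sim, str(out / "sim_config.yaml"))
        return {"sv_calls": len(sv_calls), "snv_calls": len(snv_calls),
                "loops": len(tl.loops), "tss": len(tl.tss)}

    @stage("sv_hrr")
    def _sv():
        filtered = sv_hrr.filter_sv(state["sv_calls"])
        by_type = sv_hrr.call_sv_hrrs(
            filtered, state["genome"], cfg.seed_min_donors, cfg.candidate_min_donors
        )
        state["sv_hrrs"] = by_type
        flat = [r for t in sv_hrr.SV_TYPES for r in by_type[t]]
        sv_hrr.write_hrr_table(flat + by_type["MERGED"], str(out / "sv_hrrs.tsv"))
        return {
            "filtered_calls": len(filtered),
            **{t: len(by_type[t]) for t in sv_hrr.SV_TYPES},
            "merged": len(by_type["MERGED"]),
        }

    @stage("snv_hrr")
    def _snv():
        clusters = snv_hrr.cluster_mutations(state["snv_calls"], cfg.cluster_gap)
        snv_hrr.attach_covariates(clusters, state["tracks"], state["genome"])
        fit, tests = snv_hrr.fit_and_test(clusters, fdr=cfg.fdr)
        state["snv_tests"] = tests
        sig = [t for t in tests if t.q < cfg.fdr]
        return {"clusters": len(clusters), "significant": len(sig),
                "theta": round(fit.theta, 3)}

    @stage("annotate")
    def _annotate():
        hrr_triplets = []
        i = 0
        for t in sv_hrr.SV_TYPES:
            for r in state["sv_hrrs"][t]:
                hrr_triplets.append((f"HRR_{i}", t, r.interval))
                i += 1
        for tst in state["snv_tests"]:
            if tst.q < cfg.fdr:
                hrr_triplets.append((f"HRR_{i}", "SNV", tst.cluster.interval))
                i += 1
        tl = state["tl"]
        enhancers = enh_mod.define_hrr_enhancers(hrr_triplets, tl.h3k27ac)
        eligible = enh_mod.define_core_regions(
            [e for e in enhancers if e.hrr_associated], tl.h3k4me1, tl.atac
        )
        state["enhancers"] = enhancers
        state["eligible"] = eligible
        enh_mod.write_enhancer_table(enhancers, str(out / "enhancers.tsv"))
        return {
            "hrrs": len(hrr_triplets),
            "enhancers": len(enhancers),
            "hrr_associated": sum(e.hrr_associated for e in enhancers),
            "screen_eligible": len(eligible),
            "core_regions": sum(len(e.core_regions) for e in eligible),
        }

    @stage("design")
    def _design():
        cores = [
            (e.enhancer_id, f"{e.enhancer_id}_c{i}", c)
            for e in state["eligible"]
            for i, c in enumerate(e.core_regions)
        ]
        lib = guides_mod.design_library(cores, state["genome"], cfg.bin_size)
        controls = guides_mod.make_controls(
            state["genome"], cfg.n_controls, seed=cfg.sim.seed
        )
        state["library"] = lib + controls
        guides_mod.write_library(state["library"], str(out / "library.tsv"))
        return {"targeting_guides": len(lib), "controls": len(controls)}

    @stage("screen")
    def _screen():
        lib = state["library"]
        enh_ids = sorted({g.enhancer_id for g in lib if not g.is_control})
        rng = cfg.sim.rng("screen_effects")
        k = min(cfg.n_screen_hits, len(enh_ids))
        chosen = sorted(rng.choice(len(enh_ids), size=k, replace=False))
        effects = {enh_ids[i]: cfg.screen_effect for i in chosen}
        cfg.sim.screen.planted_effects = effects
        cm, truth = sim.gen_screen_counts(cfg.sim, lib)
        sim.write_counts_tsv(cm, str(out / "screen_counts.tsv"))
        lfc, results = screen_mod.run_screen(
            cm, "positive", alpha=cfg.rra_alpha, n_perm=cfg.n_perm, seed=cfg.sim.seed
        )
        state["screen_results"] = results
        state["screen_truth"] = truth
        hits = [r for r in results if r.significant]
        state["screen_hits"] = hits
        return {
            "enhancers_tested": len(results),
            "planted": len(effects),
            "hits_fdr05": len(hits),
        }

    @stage("targets")
    def _targets():
        tl = state["tl"]
        kept = loops_mod.filter_loops(tl.loops)
        promoters = loops_mod.promoter_windows(
            tl.tss, chrom_lengths=cfg.sim.chrom_lengths
        )
        hit_ids = {r.enhancer_id for r in state.get("screen_hits", [])}
        enh_pairs = [
            (e.enhancer_id, e.interval)
            for e in state["eligible"]
            if not hit_ids or e.enhancer_id in hit_ids
        ]
        links = loops_mod.assign_targets(kept, enh_pairs, promoters)
        loops_mod.write_links(links, str(out / "target_links.tsv"))
        co_defined = [
            e.interval for e in state["eligible"] if e.core_regions
        ]
        n_loops, n_ep = loops_mod.count_ep_pairs(tl.loops, co_defined, tl.tss)
        return {
            "loops": len(tl.loops), "loops_kept": len(kept),
            "links": len(links), "ep_loops": n_ep,
        }

    @stage("mutsig")
    def _mutsig():
        regions = [e.interval for e in state["enhancers"] if e.hrr_associated]
        matrix, skipped = mutsig_mod.build_sbs_matrix(
            state["snv_calls"], state["genome"], regions,
            sample_of=lambda d: "cohort",
        )
        if matrix.shape[1] == 0 or matrix.to_numpy().sum() < 50:
            return {"substitutions": int(matrix.to_numpy().sum()), "skipped": skipped,
                    "note": "too few enhancer substitutions for extraction"}
        k = min(cfg.mutsig_k, matrix.shape[1])
        sigs, exposures = mutsig_mod.extract_signatures(
            matrix, k=k, seed=cfg.sim.seed, n_restarts=cfg.mutsig_restarts,
            max_iter=500,
        )
        catalog = mutsig_mod.load_builtin_catalog()
        matches = [mutsig_mod.match_cosmic(s, catalog)[0] for s in sigs]
        state["signature_matches"] = matches
        return {
            "substitutions": int(matrix.to_numpy().sum()),
            "skipped": skipped,
            "signatures": k,
            "top_matches": [[lbl, round(cos, 4)] for lbl, cos in matches],
        }

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
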