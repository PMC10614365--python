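"""Define HRR-associated enhancers and evaluate their presumed targets.

Intersects qualifying HRRs (candidate SV-HRRs plus significant SNV
clusters) with H3K27ac peaks to call HRR-associated enhancers, requires
H3K4me1 for screen eligibility, and narrows eligible enhancers to ATAC
core regions. Presumed target genes (TSS within 1 Mb) of HRR-associated
enhancers are compared with targets of HRR-unrelated enhancers on a
synthetic CRISPR enrichment score (planted target genes shifted +1.5) via
a two-sided Mann-Whitney U test per HRR type. Writes results/enhancers.tsv
and results/target_score_tests.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from hrrscan import snv_hrr, sv_hrr
from hrrscan.enhancers import (
    assign_presumed_targets,
    compare_enrichment_scores,
    define_core_regions,
    define_hrr_enhancers,
    write_enhancer_table,
)
from hrrscan.pipeline import demo_config
from hrrscan.simulate import (
    gen_genome,
    gen_snv_callsets,
    gen_sv_callsets,
    gen_tracks_and_loops,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def hrr_triplets(cfg, genome):
    calls, _ = gen_sv_callsets(cfg)
    by_type = sv_hrr.call_sv_hrrs(sv_hrr.filter_sv(calls), genome)
    snvs, tracks, _ = gen_snv_callsets(cfg, genome)
    clusters = snv_hrr.cluster_mutations(snvs)
    snv_hrr.attach_covariates(clusters, tracks, genome)
    _, tests = snv_hrr.fit_and_test(clusters)
    out = []
    for t in sv_hrr.SV_TYPES:
        for r in by_type[t]:
            out.append((f"HRR_{len(out)}", t, r.interval))
    for t in tests:
        if t.q < 0.05:
            out.append((f"HRR_{len(out)}", "SNV", t.cluster.interval))
    return out


def main(seed: int = 7) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = demo_config(seed).sim
    genome = gen_genome(cfg)
    hrrs = hrr_triplets(cfg, genome)
    # extra decoy genes give the HRR-unrelated null group statistical mass
    tl = gen_tracks_and_loops(cfg, n_decoy_genes=60)
    enhancers = define_hrr_enhancers(hrrs, tl.h3k27ac)
    associated = [e for e in enhancers if e.hrr_associated]
    eligible = define_core_regions(associated, tl.h3k4me1, tl.atac)
    print(f"{len(hrrs)} HRRs x {len(tl.h3k27ac)} H3K27ac peaks -> "
          f"{len(associated)} HRR-associated enhancers, {len(eligible)} screen-"
          f"eligible, {sum(len(e.core_regions) for e in eligible)} core regions")
    write_enhancer_table(enhancers, str(OUT / "enhancers.tsv"))

    # functional evaluation on synthetic CRISPR enrichment scores: genes of
    # the planted SV-HRR enhancers carry a +2 shift (growth effect); all
    # other genes, including decoys inside the 1 Mb windows, are null
    assignments = assign_presumed_targets(enhancers, tl.tss)
    rng = np.random.default_rng(seed)
    n_sv = len(cfg.planted_hrrs)
    planted_genes = {
        g for g, tag in tl.truth.enhancer_genes.items()
        if int(tag.split("_")[1]) < n_sv
    }
    scores = {
        r.gene: float(rng.normal() + (2.0 if r.gene in planted_genes else 0.0))
        for r in tl.tss
    }
    results = compare_enrichment_scores(assignments, scores)
    frac = {
        t: np.mean(
            [g in planted_genes for g in {a.gene for a in assignments if a.group == t}]
        )
        for t in {a.group for a in assignments}
    }
    df = pd.DataFrame(
        [
            {
                "hrr_type": r.hrr_type,
                "U": r.u_statistic,
                "p_value": r.p_value,
                "n_targets": r.n_hrr,
                "n_unrelated": r.n_unrelated,
                "frac_targets_with_true_effect": round(frac.get(r.hrr_type, 0.0), 3),
            }
            for r in results
        ]
    )
    df.to_csv(OUT / "target_score_tests.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("note: 1 Mb windows sweep in many decoy genes, so at this toy scale "
          "the rank test is diluted; the test machinery itself is checked "
          "exactly against enumeration and permutation oracles in the suite")
    print(f"wrote {OUT / 'enhancers.tsv'} and {OUT / 'target_score_tests.tsv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
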