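"""Assign target genes to enhancers from significant chromatin loops.

Filters loops to intra-chromosomal contacts with anchor-midpoint distance
in [20 kb, 2 Mb], builds strand-aware promoter windows (20 kb upstream,
5 kb downstream of the TSS), and links an enhancer to a gene whenever one
loop anchor overlaps the promoter window and the other the enhancer. Also
reports the global enhancer-promoter loop census with the narrower
TSS +/- 3 kb promoter definition. Writes results/target_links.tsv.
"""

import importlib
import sys
from pathlib import Path

from hrrscan.loops import (
    assign_targets,
    count_ep_pairs,
    filter_loops,
    promoter_windows,
    write_links,
)
from hrrscan.pipeline import demo_config
from hrrscan.simulate import gen_genome, gen_tracks_and_loops
from hrrscan.enhancers import define_core_regions, define_hrr_enhancers

annotate = importlib.import_module("04_annotate_enhancers")

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 7) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = demo_config(seed).sim
    genome = gen_genome(cfg)
    hrrs = annotate.hrr_triplets(cfg, genome)
    tl = gen_tracks_and_loops(cfg)
    enhancers = define_hrr_enhancers(hrrs, tl.h3k27ac)
    eligible = define_core_regions(
        [e for e in enhancers if e.hrr_associated], tl.h3k4me1, tl.atac
    )
    kept = filter_loops(tl.loops)
    print(f"{len(tl.loops)} loops, {len(kept)} inside the 20 kb-2 Mb band")
    promoters = promoter_windows(tl.tss, chrom_lengths=cfg.chrom_lengths)
    links = assign_targets(kept, [(e.enhancer_id, e.interval) for e in eligible], promoters)
    print(f"{len(links)} enhancer->gene links "
          f"({sum(l.shared_anchor for l in links)} with shared promoter anchors)")
    n_loops, n_ep = count_ep_pairs(
        tl.loops, [e.interval for e in eligible], tl.tss
    )
    print(f"E-P census (TSS +/- 3 kb): {n_ep}/{n_loops} loops are enhancer-promoter")
    write_links(links, str(OUT / "target_links.tsv"))
    print(f"wrote {OUT / 'target_links.tsv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
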