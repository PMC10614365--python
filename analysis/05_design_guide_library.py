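"""Design the intersected-tiling sgRNA library over enhancer core regions.

Each core region is cut into 100 bp bins; all NGG-adjacent 20-mers cutting
inside a bin are enumerated, filtered (no TTTT, GC in [20%, 80%]) and
scored; the best guide per bin enters the library, plus 1000 non-targeting
controls verified to have no exact genome match on either strand. Writes
results/guide_library.tsv.
"""

import importlib
import sys
from pathlib import Path

from hrrscan.guides import design_library, make_controls, write_library
from hrrscan.pipeline import demo_config
from hrrscan.simulate import gen_genome, gen_tracks_and_loops
from hrrscan.enhancers import define_core_regions, define_hrr_enhancers

annotate = importlib.import_module("04_annotate_enhancers")

OUT = Path(__file__).resolve().parent.parent / "results"


def eligible_cores(seed: int):
    cfg = demo_config(seed).sim
    genome = gen_genome(cfg)
    hrrs = annotate.hrr_triplets(cfg, genome)
    tl = gen_tracks_and_loops(cfg)
    enhancers = define_hrr_enhancers(hrrs, tl.h3k27ac)
    eligible = define_core_regions(
        [e for e in enhancers if e.hrr_associated], tl.h3k4me1, tl.atac
    )
    cores = [
        (e.enhancer_id, f"{e.enhancer_id}_c{i}", c)
        for e in eligible
        for i, c in enumerate(e.core_regions)
    ]
    return cfg, genome, cores


def main(seed: int = 7) -> None:
    OUT.mkdir(exist_ok=True)
    cfg, genome, cores = eligible_cores(seed)
    lib = design_library(cores, genome)
    controls = make_controls(genome, 1000, seed=seed)
    per_enh = {}
    for g in lib:
        per_enh[g.enhancer_id] = per_enh.get(g.enhancer_id, 0) + 1
    counts = sorted(per_enh.values())
    print(f"{len(cores)} core regions -> {len(lib)} targeting guides "
          f"(per-enhancer min {counts[0]}, max {counts[-1]}), "
          f"{len(controls)} non-targeting controls")
    write_library(lib + controls, str(OUT / "guide_library.tsv"))
    print(f"wrote {OUT / 'guide_library.tsv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
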