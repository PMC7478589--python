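"""Simulate the serial-founder range expansion and write its raw inputs.

Runs the default desk-scale expansion (8 demes x 100 diploids, 10 founders
per wave, additive selection s = 0.01 on 1000 deleterious loci) and writes
the VCF, population map, outgroup panel, score table and truth annotations
under scratch/expansion_inputs/.  Downstream scripts consume these files exactly as
they would consume a real reduced-representation dataset.
"""

import pathlib

import numpy as np

from expansionload.simulate import (ExpansionSimConfig, gen_outgroup_panel,
                                    gen_range_expansion)
from expansionload.vcfio import (write_outgroups, write_popmap, write_scores,
                                 write_vcf)

SEED = 20260925
OUT = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "expansion_inputs"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ExpansionSimConfig(seed=SEED)
    gm, annotations, popmap = gen_range_expansion(cfg)
    rng = np.random.default_rng(SEED)
    gm.sites["mean_depth"] = rng.integers(10, 60, size=gm.n_sites).astype(float)
    outgroups = gen_outgroup_panel(gm.sites, error_rate=0.01,
                                   missing_rate=0.05, seed=SEED + 1)
    write_vcf(gm, OUT / "genotypes.vcf")
    write_popmap(popmap, OUT / "popmap.tsv")
    write_outgroups(outgroups, OUT / "outgroups.tsv")
    write_scores(annotations[["chrom", "pos", "score"]], OUT / "scores.tsv")
    annotations.to_csv(OUT / "annotations.tsv", sep="\t", index=False)
    print(f"simulated {gm.n_individuals} individuals x {gm.n_sites} sites "
          f"across {cfg.n_demes} demes (seed {SEED})")
    print(f"wrote inputs under {OUT}")


if __name__ == "__main__":
    main()
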