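"""Deleterious-load geography: polarization, load counts, piN/piS, DAF.

Polarizes the simulated SNPs against the three-outgroup panel, classifies
deleterious variants (score <= -2.5 among nonsynonymous sites), counts the
recessive (homozygous-derived) and total (2*N_homo + N_het) load per
individual, computes piN/piS per deme, and fits the load regressions
(recessive/total load ~ distance, piN/piS ~ distance / Tajima's D / piS).
"""

import pathlib

import pandas as pd

from expansionload.genotypes import filter_individuals, filter_sites
from expansionload.load import (classify_deleterious, daf_spectra,
                                load_counts, load_regressions, pin_pis,
                                polarize_table)
from expansionload.stats import diversity
from expansionload.vcfio import (read_outgroups, read_popmap, read_scores,
                                 read_vcf)

SEED = 20260925
RAW = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "expansion_inputs"
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "expansion"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    gm = read_vcf(RAW / "genotypes.vcf")
    popmap = read_popmap(RAW / "popmap.tsv")
    gm, _ = filter_sites(gm, "initial")
    gm, _ = filter_individuals(gm)
    gm, _ = filter_sites(gm, "final")

    annotations = pd.read_csv(RAW / "annotations.tsv", sep="\t")
    annotations = annotations.merge(gm.sites[["chrom", "pos"]],
                                    on=["chrom", "pos"], how="right")
    outgroups = read_outgroups(RAW / "outgroups.tsv")
    scores = read_scores(RAW / "scores.tsv")

    ancestral = polarize_table(gm.sites, outgroups)
    n_pol = (ancestral != "unknown").sum()
    print(f"polarized {n_pol}/{gm.n_sites} sites via the outgroup panel")

    flags = classify_deleterious(annotations.drop(columns=["score"]), scores)
    counts = load_counts(gm, ancestral, flags, popmap)
    counts["per_individual"].to_csv(OUT / "load_individual.tsv", sep="\t",
                                    index=False)
    counts["per_population"].to_csv(OUT / "load_population.tsv", sep="\t",
                                    index=False)
    print(f"{flags.sum()} deleterious sites; "
          f"{100 * counts['het_fraction']:.1f}% of deleterious genotypes are "
          "heterozygous")

    pin = pin_pis(gm, annotations, popmap)
    pin.to_csv(OUT / "pin_pis.tsv", sep="\t", index=False)

    div = diversity(gm, popmap)
    table = load_regressions(counts, pin, div, popmap)
    table.to_csv(OUT / "load_regressions.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    daf = daf_spectra(gm, ancestral, annotations, popmap,
                      deleterious_flags=flags, normalize_n=100)
    daf["summary"].to_csv(OUT / "daf_summary.tsv", sep="\t", index=False)
    if "kruskal_regions" in daf["tests"]:
        k = daf["tests"]["kruskal_regions"]
        print(f"Kruskal-Wallis deleterious DAF across regions: "
              f"H = {k['H']:.2f}, p = {k['p']:.3g}")


if __name__ == "__main__":
    main()
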