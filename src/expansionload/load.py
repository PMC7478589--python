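"""Deleterious-load analysis: polarization, piN/piS, load counts, DAF spectra.

Derived alleles are identified against three outgroup genomes: the ancestral
state is the allele homozygous in at least two agreeing outgroups, provided
it matches one of the two focal alleles; anything else leaves the site
unpolarized and excluded from derived-allele analyses.  A nonsynonymous
variant is called deleterious when its externally supplied effect score is
-2.5 or less (scores are consumed, never computed here).

Load is summarised per individual as the count of homozygous-derived
deleterious genotypes (recessive load, N_homo) and the total number of
derived deleterious alleles N_total = 2*N_homo + N_het (additive/total
load); piN/piS contrasts nucleotide diversity at 0-fold versus 4-fold
degenerate sites.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import MISSING, GenotypeMatrix, PopulationMap
from .sfs import project_counts
from .stats import ols_report, pairwise_wilcoxon

__all__ = ["polarize", "polarize_table", "classify_deleterious", "pin_pis",
           "load_counts", "daf_spectra", "load_regressions", "derived_counts"]

DELETERIOUS_THRESHOLD = -2.5


def polarize(ref: str, alt: str, outgroups) -> str:
    """Ancestral state of one site from three outgroup genotypes.

    ``outgroups`` are two-letter genotype strings ('AA', 'AC', 'NN', ...).
    Returns 'ref', 'alt' or 'unknown' per the two-agreeing-homozygous-
    outgroups rule.
    """
    votes: dict[str, int] = {}
    for og in outgroups:
        if not isinstance(og, str) or len(og) != 2 or "N" in og.upper():
            continue
        a, b = og[0].upper(), og[1].upper()
        if a != b:
            continue  # heterozygous outgroup: no vote
        votes[a] = votes.get(a, 0) + 1
    for allele, n in votes.items():
        if n >= 2:
            if allele == ref.upper():
                return "ref"
            if allele == alt.upper():
                return "alt"
            return "unknown"  # agreeing outgroups do not match a focal allele
    return "unknown"


def polarize_table(sites: pd.DataFrame, outgroups: pd.DataFrame) -> pd.Series:
    """Vectorised polarization of a site table against an outgroup table."""
    og = outgroups.set_index(["chrom", "pos"])
    out = []
    for _, site in sites.iterrows():
        key = (site["chrom"], site["pos"])
        if key not in og.index:
            out.append("unknown")
            continue
        row = og.loc[key]
        out.append(polarize(site["ref"], site["alt"],
                            (row["og1"], row["og2"], row["og3"])))
    return pd.Series(out, index=sites.index, name="ancestral")


def classify_deleterious(annotations: pd.DataFrame, scores: pd.DataFrame | None = None,
                         *, threshold: float = DELETERIOUS_THRESHOLD) -> np.ndarray:
    """Deleterious flags: nonsynonymous AND score <= threshold (-2.5 or less).

    ``annotations`` needs columns (chrom, pos, functional_class) and either a
    ``score`` column or a separate ``scores`` table (chrom, pos, score).
    Scores attached to non-nonsynonymous sites are ignored with a warning.
    """
    ann = annotations
    if scores is not None:
        ann = ann.merge(scores[["chrom", "pos", "score"]], on=["chrom", "pos"],
                        how="left", suffixes=("_ann", ""))
    if "score" not in ann.columns:
        raise ValueError("no deleteriousness scores available")
    score = ann["score"].to_numpy(dtype=float)
    nonsyn = (ann["functional_class"] == "nonsynonymous").to_numpy()
    scored_elsewhere = ~nonsyn & np.isfinite(score) & (score != 0)
    if scored_elsewhere.any():
        warnings.warn(f"{int(scored_elsewhere.sum())} scores on non-nonsynonymous "
                      "sites ignored")
    with np.errstate(invalid="ignore"):
        return nonsyn & (np.nan_to_num(score, nan=np.inf) <= threshold)


def pin_pis(gm: GenotypeMatrix, annotations: pd.DataFrame,
            popmap: PopulationMap) -> pd.DataFrame:
    """piN (0-fold sites), piS (4-fold sites) and their ratio per population.

    pi is the per-site mean pairwise difference; 2-fold degenerate sites are
    excluded from both classes.  The ratio is NaN (with a warning) when piS
    is 0 or no 4-fold site exists.  Folded quantity: polarization is not
    needed and does not change the result.
    """
    ann = annotations.set_index(["chrom", "pos"])
    deg = ann.reindex(pd.MultiIndex.from_frame(gm.sites[["chrom", "pos"]]))[
        "degeneracy"].to_numpy(dtype=float)
    is_n = deg == 0
    is_s = deg == 4
    if not is_s.any():
        warnings.warn("no 4-fold degenerate sites; piN/piS undefined")
    rows = []
    for pop in popmap.populations:
        members = popmap.members(pop, gm.individuals)
        d, c = gm.allele_counts(members)
        with np.errstate(divide="ignore", invalid="ignore"):
            pi_site = 2 * d * (c - d) / (c * (c - 1.0))
        ok = c > 1
        pi_n = float(np.nanmean(pi_site[is_n & ok])) if (is_n & ok).any() else np.nan
        pi_s = float(np.nanmean(pi_site[is_s & ok])) if (is_s & ok).any() else np.nan
        ratio = pi_n / pi_s if pi_s and np.isfinite(pi_s) and pi_s > 0 else np.nan
        rows.append({"population": pop, "pi_n": pi_n, "pi_s": pi_s,
                     "pin_pis": ratio})
    return pd.DataFrame(rows)


def derived_counts(gm: GenotypeMatrix, ancestral: pd.Series | np.ndarray
                   ) -> np.ndarray:
    """Per-genotype derived allele-copy counts (MISSING propagated).

    ``ancestral`` holds 'ref'/'alt'/'unknown' per site; sites with unknown
    ancestral state are returned as MISSING everywhere.
    """
    anc = np.asarray(pd.Series(ancestral))
    v = gm.values
    flipped = np.where(v == MISSING, MISSING, 2 - v)
    out = np.where(anc == "ref", v, np.where(anc == "alt", flipped, MISSING))
    return out.astype(np.int8)


def load_counts(gm: GenotypeMatrix, ancestral, deleterious_flags: np.ndarray,
                popmap: PopulationMap) -> dict:
    """Per-individual recessive and total deleterious load, plus group tests.

    Counts run over polarized deleterious sites only: N_homo homozygous
    derived, N_het heterozygous, N_total = 2*N_homo + N_het.  Returns the
    per-individual table, population and region means, the overall fraction
    of deleterious genotypes that are heterozygous, and pairwise Wilcoxon
    tests (BH-corrected) between regions on the individual values.
    """
    der = derived_counts(gm, ancestral)
    use = np.asarray(deleterious_flags, dtype=bool)
    anc_known = np.asarray(pd.Series(ancestral)).astype(str) != "unknown"
    use = use & anc_known
    if not use.any():
        warnings.warn("no polarized deleterious sites; load counts are zero")
    sub = der[:, use]
    n_homo = (sub == 2).sum(axis=1)
    n_het = (sub == 1).sum(axis=1)
    pop_of = popmap.population_of()
    reg_of = popmap.region_of()
    per_ind = pd.DataFrame({
        "individual": gm.individuals,
        "population": [pop_of[i] for i in gm.individuals],
        "region": [reg_of[i] for i in gm.individuals],
        "n_homo": n_homo,
        "n_het": n_het,
        "n_total": 2 * n_homo + n_het,
    })
    per_pop = per_ind.groupby("population", sort=False)[
        ["n_homo", "n_het", "n_total"]].mean().reset_index()
    per_region = per_ind.groupby("region", sort=False)[
        ["n_homo", "n_het", "n_total"]].mean().reset_index()
    total_geno = int((sub > 0).sum())
    het_fraction = float(n_het.sum() / (n_het.sum() + (sub == 2).sum())) \
        if total_geno else np.nan
    tests = {}
    if per_ind["region"].nunique() > 1:
        for metric in ("n_homo", "n_total"):
            groups = {r: g[metric].to_numpy()
                      for r, g in per_ind.groupby("region", sort=False)}
            tests[metric] = pairwise_wilcoxon(groups)
    return {"per_individual": per_ind, "per_population": per_pop,
            "per_region": per_region, "het_fraction": het_fraction,
            "region_tests": tests}


def daf_spectra(gm: GenotypeMatrix, ancestral, annotations: pd.DataFrame,
                popmap: PopulationMap, *, deleterious_flags: np.ndarray | None = None,
                normalize_n: int = 100) -> dict:
    """Derived allele frequencies per population and mutation category.

    Categories: synonymous, nonsynonymous, deleterious (nonsynonymous with a
    qualifying score).  Per-population DAF vectors cover polarized sites
    segregating in that population; regional spectra are hypergeometrically
    projected to ``normalize_n`` haploid copies.  Kruskal-Wallis tests run
    across regions and across populations on the deleterious DAF; pairwise
    Wilcoxon (BH) across regions.
    """
    ann = annotations.set_index(["chrom", "pos"])
    ann = ann.reindex(pd.MultiIndex.from_frame(gm.sites[["chrom", "pos"]]))
    klass = ann["functional_class"].to_numpy()
    if deleterious_flags is None:
        if "score" in ann.columns:
            deleterious_flags = classify_deleterious(ann.reset_index())
        else:
            deleterious_flags = np.zeros(gm.n_sites, dtype=bool)
    cats = {
        "synonymous": klass == "synonymous",
        "nonsynonymous": klass == "nonsynonymous",
        "deleterious": np.asarray(deleterious_flags, dtype=bool),
    }
    der = derived_counts(gm, ancestral)
    der_gm = GenotypeMatrix(np.where(der == MISSING, MISSING, der),
                            gm.sites, gm.individuals)
    daf_rows = []
    per_pop_daf: dict[tuple[str, str], np.ndarray] = {}
    for pop in popmap.populations:
        members = popmap.members(pop, gm.individuals)
        d, c = der_gm.allele_counts(members)
        region = popmap.table.loc[popmap.table["population"] == pop,
                                  "region"].iloc[0]
        for cat, mask in cats.items():
            if not mask.any():
                warnings.warn(f"category {cat!r} empty; skipped")
                continue
            sel = mask & (c > 0) & (d > 0) & (d < c)
            freqs = d[sel] / c[sel]
            per_pop_daf[(pop, cat)] = freqs
            daf_rows.append({"population": pop, "region": region,
                             "category": cat, "n_sites": int(sel.sum()),
                             "mean_daf": float(freqs.mean()) if sel.any() else np.nan})
    summary = pd.DataFrame(daf_rows)
    # regional spectra projected to normalize_n haploid copies
    spectra = {}
    for region in popmap.regions:
        pops = popmap.table.loc[popmap.table["region"] == region,
                                "population"].unique()
        rows = np.concatenate([popmap.members(p, gm.individuals) for p in pops])
        d, c = der_gm.allele_counts(rows)
        for cat, mask in cats.items():
            spec = np.zeros(normalize_n + 1)
            sel = np.flatnonzero(mask & (c >= normalize_n) & (d > 0))
            for j in sel:
                spec += project_counts(c[j], d[j], normalize_n)
            spectra[(region, cat)] = spec
    tests = {}
    del_by_region = {}
    for region in popmap.regions:
        pops = popmap.table.loc[popmap.table["region"] == region,
                                "population"].unique()
        vals = [per_pop_daf.get((p, "deleterious"), np.empty(0)) for p in pops]
        del_by_region[region] = np.concatenate(vals) if vals else np.empty(0)
    groups = [v for v in del_by_region.values() if v.size]
    if len(groups) > 1:
        h, p = sps.kruskal(*groups)
        tests["kruskal_regions"] = {"H": float(h), "p": float(p),
                                    "df": len(groups) - 1}
        tests["wilcoxon_regions"] = pairwise_wilcoxon(
            {r: v for r, v in del_by_region.items() if v.size})
    pop_groups = [per_pop_daf[(p, "deleterious")] for p in popmap.populations
                  if per_pop_daf.get((p, "deleterious"), np.empty(0)).size]
    if len(pop_groups) > 1:
        h, p = sps.kruskal(*pop_groups)
        tests["kruskal_populations"] = {"H": float(h), "p": float(p),
                                        "df": len(pop_groups) - 1}
    return {"summary": summary, "per_population_daf": per_pop_daf,
            "regional_spectra": spectra, "tests": tests}


def load_regressions(load: dict, pin: pd.DataFrame, div, popmap: PopulationMap,
                     *, exclude: list[str] | None = None) -> pd.DataFrame:
    """The load-gradient regressions, with an optional exclusion refit.

    Fits recessive load ~ distance, total load ~ distance, piN/piS ~
    distance, piN/piS ~ Tajima's D and piN/piS ~ piS on per-population
    values; when ``exclude`` is given each fit is repeated without the
    listed populations (sensitivity refit).
    """
    per_pop = load["per_population"].merge(pin, on="population")
    per_pop["distance_km"] = [popmap.distance_of(p) for p in per_pop["population"]]
    if div is not None:
        per_pop = per_pop.merge(
            div.per_population[["population", "tajimas_d"]], on="population")
    specs = [("n_homo", "distance_km"), ("n_total", "distance_km"),
             ("pin_pis", "distance_km"), ("pin_pis", "pi_s")]
    if "tajimas_d" in per_pop.columns:
        specs.insert(3, ("pin_pis", "tajimas_d"))
    rows = []
    subsets = [("all", per_pop)]
    if exclude:
        subsets.append(("excluded", per_pop[~per_pop["population"].isin(exclude)]))
    for label, sub in subsets:
        for resp, pred in specs:
            if sub[resp].isna().all() or sub[pred].isna().all():
                continue
            try:
                rep = ols_report(sub[pred], sub[resp])
            except ValueError:
                continue
            rep.update({"response": resp, "predictor": pred, "subset": label})
            rows.append(rep)
    return pd.DataFrame(rows)[["response", "predictor", "subset", "slope",
                               "intercept", "r", "r2", "p", "n"]]
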