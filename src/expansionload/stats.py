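"""Diversity, differentiation, ancestry and isolation-by-distance statistics.

Implements the summary statistics used to characterise a range expansion:

* observed/expected heterozygosity and per-SNP nucleotide diversity;
* Weir & Cockerham's FST estimator theta (ratio-of-sums over sites);
* the population-specific differentiation coefficient beta_ST built from
  allele-matching proportions, whose negative values flag candidate
  ancestral populations, with a site bootstrap for confidence intervals;
* dataset-wide singleton counts under rarefaction (repeated subsampling to a
  common number of individuals per population);
* Tajima's D from a one-population SFS;
* Mantel tests and ordinary least-squares gradient regressions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import MISSING, GenotypeMatrix, PopulationMap
from .sfs import sfs_1d

__all__ = ["diversity", "wc_fst", "fst_matrix", "beta_st",
           "singleton_rarefaction", "tajimas_d", "mantel", "ols_report",
           "ibd_and_gradient_report", "DiversitySummary", "bh_adjust",
           "pairwise_wilcoxon"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def pairwise_wilcoxon(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests with BH correction across pairs."""
    names = list(groups)
    rows = []
    for a, b in itertools.combinations(names, 2):
        stat, p = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"group1": a, "group2": b, "statistic": stat, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    per_population: pd.DataFrame   # population, n, Ho, He, pi, tajimas_d
    fst: pd.DataFrame | None = None          # pop1, pop2, theta
    beta_st: pd.DataFrame | None = None      # population, beta, ci_low, ci_high
    singletons: pd.DataFrame | None = None


def diversity(gm: GenotypeMatrix, popmap: PopulationMap, *,
              compute_tajimas_d: bool = True) -> DiversitySummary:
    """Per-population Ho, unbiased He, per-SNP pi, and Tajima's D.

    He uses the small-sample correction (2n/(2n-1)) * (1 - sum p^2); pi is
    the per-site mean pairwise difference averaged over SNP sites, which for
    biallelic SNPs coincides with unbiased He at fully called sites.
    Tajima's D is computed from the population's folded SFS over sites fully
    called within the population.
    """
    popmap.validate_against(gm)
    rows = []
    for pop in popmap.populations:
        members = popmap.members(pop, gm.individuals)
        if members.size == 0:
            raise ValueError(f"population {pop!r} has no genotyped individuals")
        v = gm.values[members]
        called = v != MISSING
        n_called = called.sum(axis=0)
        ok = n_called > 0
        het = ((v == 1) & called).sum(axis=0)
        ho = float((het[ok] / n_called[ok]).mean()) if ok.any() else np.nan
        alt = np.where(called, v, 0).sum(axis=0)
        copies = 2 * n_called
        with np.errstate(divide="ignore", invalid="ignore"):
            p = alt / copies
            he_site = (copies / (copies - 1)) * (1 - p**2 - (1 - p)**2)
            pi_site = 2 * alt * (copies - alt) / (copies * (copies - 1))
        ok2 = copies > 1
        he = float(he_site[ok2].mean()) if ok2.any() else np.nan
        pi = float(pi_site[ok2].mean()) if ok2.any() else np.nan
        d = np.nan
        if compute_tajimas_d and members.size >= 2:
            xi = sfs_1d(gm, popmap, pop)
            d = tajimas_d(xi)
        rows.append({"population": pop, "n": members.size, "Ho": ho, "He": he,
                     "pi": pi, "tajimas_d": d})
    return DiversitySummary(per_population=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(gm: GenotypeMatrix, rows1: np.ndarray, rows2: np.ndarray):
    """Per-site Weir-Cockerham (1984) variance components a, b, c for r=2.

    Notation per site: n_i diploids called in population i, p_i the ALT
    frequency, h_i the observed heterozygote proportion; n_bar, p_bar the
    weighted means, n_c the variance-corrected sample size, s2 the variance
    of p over populations, h_bar the mean heterozygosity.
    a = between-population, b = between-individual-within-population,
    c = within-individual; theta = sum(a) / sum(a + b + c).
    """
    out = []
    for rows in (rows1, rows2):
        v = gm.values[rows]
        called = v != MISSING
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, v, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = alt / (2 * n)
            h = ((v == 1) & called).sum(axis=0) / n
        out.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = out
    r = 2.0
    valid = (n1 > 0) & (n2 > 0)
    n_bar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar)**2 + n2 * (p2 - p_bar)**2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                   - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                     - (r - 1) / r * s2
                                     - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
    return a, b, c, valid


def wc_fst(gm: GenotypeMatrix, popmap: PopulationMap, pop1: str, pop2: str) -> float:
    """Multi-site Weir & Cockerham theta (ratio of summed variance components)."""
    rows1 = popmap.members(pop1, gm.individuals)
    rows2 = popmap.members(pop2, gm.individuals)
    if rows1.size == 0 or rows2.size == 0:
        raise ValueError("need two non-empty populations")
    a, b, c, valid = _wc_components(gm, rows1, rows2)
    denom = np.nansum((a + b + c)[valid])
    if denom == 0 or not np.isfinite(denom):
        return np.nan
    return float(np.nansum(a[valid]) / denom)


def fst_matrix(gm: GenotypeMatrix, popmap: PopulationMap,
               pops: list[str] | None = None) -> pd.DataFrame:
    pops = pops or popmap.populations
    out = pd.DataFrame(np.zeros((len(pops), len(pops))), index=pops, columns=pops)
    for p1, p2 in itertools.combinations(pops, 2):
        theta = wc_fst(gm, popmap, p1, p2)
        out.loc[p1, p2] = out.loc[p2, p1] = theta
    return out


# ---------------------------------------------------------------------------
# beta_ST
# ---------------------------------------------------------------------------

def _matching_proportions(gm: GenotypeMatrix, popmap: PopulationMap,
                          pops: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-site within-population and mean between-population allele matching.

    Within population i the matching proportion is the probability that two
    distinct allele copies drawn without replacement are identical; between
    populations it is the probability that one copy from each matches.
    Returns (M_within (n_pops, n_sites), M_between (n_sites,)).
    """
    freqs, copies = [], []
    for pop in pops:
        rows = popmap.members(pop, gm.individuals)
        d, c = gm.allele_counts(rows)
        freqs.append((d, c))
    n_sites = gm.n_sites
    m_within = np.full((len(pops), n_sites), np.nan)
    for i, (d, c) in enumerate(freqs):
        with np.errstate(divide="ignore", invalid="ignore"):
            m_within[i] = (d * (d - 1) + (c - d) * (c - d - 1)) / (c * (c - 1))
    pairs = list(itertools.combinations(range(len(pops)), 2))
    m_between = np.zeros(n_sites)
    for i, j in pairs:
        di, ci = freqs[i]
        dj, cj = freqs[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            pi, pj = di / ci, dj / cj
        m_between += pi * pj + (1 - pi) * (1 - pj)
    m_between /= len(pairs)
    return m_within, m_between


def beta_st(gm: GenotypeMatrix, popmap: PopulationMap, *, n_boot: int = 1000,
            seed: int = 0, pops: list[str] | None = None) -> pd.DataFrame:
    """Population-specific beta_i = (M_i - M_B) / (1 - M_B) with bootstrap CIs.

    Matching proportions are ratio-averaged over sites; the bootstrap
    resamples sites.  Negative beta flags candidate ancestral populations
    (excess private low/intermediate-frequency variation).
    """
    pops = pops or popmap.populations
    if len(pops) < 2:
        raise ValueError("beta_ST needs at least two populations")
    m_within, m_between = _matching_proportions(gm, popmap, pops)
    valid = np.isfinite(m_between) & np.all(np.isfinite(m_within), axis=0)
    m_within = m_within[:, valid]
    m_between = m_between[valid]

    def betas(site_idx):
        mi = m_within[:, site_idx].mean(axis=1)
        mb = m_between[site_idx].mean()
        return (mi - mb) / (1 - mb)

    all_sites = np.arange(m_between.size)
    point = betas(all_sites)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, len(pops)))
    for b in range(n_boot):
        boot[b] = betas(rng.integers(0, all_sites.size, size=all_sites.size))
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    return pd.DataFrame({"population": pops, "beta": point,
                         "ci_low": lo, "ci_high": hi})


# ---------------------------------------------------------------------------
# singletons under rarefaction
# ---------------------------------------------------------------------------

def singleton_rarefaction(gm: GenotypeMatrix, popmap: PopulationMap, *,
                          subsample: int = 13, reps: int = 200, seed: int = 0
                          ) -> dict:
    """Dataset-wide singleton counts per population under rarefaction.

    Every replicate subsamples ``subsample`` individuals from each population
    (populations below that size are dropped with a warning); a singleton is
    a variant whose minor allele is carried by exactly one individual across
    the whole subsampled dataset and it is attributed to that individual's
    population.  Returns per-population mean +/- sd over replicates, regional
    means, and pairwise Wilcoxon tests (BH-corrected) between regions.
    """
    popmap.validate_against(gm)
    members = {}
    for pop in popmap.populations:
        rows = popmap.members(pop, gm.individuals)
        if rows.size < subsample:
            warnings.warn(f"population {pop!r} has {rows.size} < {subsample} "
                          "individuals; dropped from rarefaction")
            continue
        members[pop] = rows
    if not members:
        raise ValueError(f"no population reaches the subsample size {subsample}")
    region_of = {p: popmap.table.loc[popmap.table["population"] == p,
                                     "region"].iloc[0] for p in members}
    rng = np.random.default_rng(seed)
    pops = list(members)
    counts = np.zeros((reps, len(pops)), dtype=int)
    for rep in range(reps):
        chosen = np.concatenate([rng.choice(members[p], size=subsample,
                                            replace=False) for p in pops])
        owner = np.repeat(np.arange(len(pops)), subsample)
        v = gm.values[chosen]
        called = v != MISSING
        alt = np.where(called, v, 0).sum(axis=0)
        copies = 2 * called.sum(axis=0)
        minor_is_alt = 2 * alt <= copies
        minor = np.where(minor_is_alt, v, np.where(called, 2 - v, 0))
        carrier_count = ((minor > 0) & called).sum(axis=0)
        polymorphic = (alt > 0) & (alt < copies)
        singleton_sites = np.flatnonzero(polymorphic & (carrier_count == 1))
        for s in singleton_sites:
            col = v[:, s]
            carrier = np.flatnonzero((np.where(minor_is_alt[s], col, 2 - col) > 0)
                                     & (col != MISSING))[0]
            counts[rep, owner[carrier]] += 1
    per_pop = pd.DataFrame({
        "population": pops,
        "region": [region_of[p] for p in pops],
        "mean_singletons": counts.mean(axis=0),
        "sd_singletons": counts.std(axis=0, ddof=1),
    })
    regions = sorted(set(region_of.values()))
    regional = {r: counts[:, [i for i, p in enumerate(pops)
                              if region_of[p] == r]].sum(axis=1)
                for r in regions}
    tests = pairwise_wilcoxon(regional) if len(regions) > 1 else pd.DataFrame()
    regional_means = pd.DataFrame({
        "region": regions,
        "mean_singletons": [regional[r].mean() for r in regions],
        "sd_singletons": [regional[r].std(ddof=1) for r in regions],
    })
    return {"per_population": per_pop, "per_region": regional_means,
            "tests": tests, "replicate_counts": counts, "populations": pops}


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajimas_d(xi: np.ndarray) -> float:
    """Tajima's D from a one-population SFS (folded or unfolded).

    D = (pi - theta_W) / sqrt(e1*S + e2*S*(S-1)) with the standard a1, a2,
    b1, b2, c1, c2, e1, e2 constants.  Needs n >= 4 sampled copies; returns
    NaN with a warning when there are no segregating sites.
    """
    xi = np.asarray(xi, dtype=float)
    n = len(xi) - 1
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sampled copies")
    s = xi[1:n].sum()
    if s <= 0:
        warnings.warn("no segregating sites; Tajima's D undefined")
        return np.nan
    i = np.arange(1, n)
    # works for folded input too: i*(n-i) is symmetric under i -> n-i
    pi = (i * (n - i) * xi[1:n]).sum() * 2.0 / (n * (n - 1))
    a1 = (1.0 / np.arange(1, n)).sum()
    a2 = (1.0 / np.arange(1, n)**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    theta_w = s / a1
    return float((pi - theta_w) / np.sqrt(e1 * s + e2 * s * (s - 1)))


# ---------------------------------------------------------------------------
# Mantel test and regressions
# ---------------------------------------------------------------------------

def mantel(d1: pd.DataFrame, d2: pd.DataFrame, *, perms: int = 10_000,
           seed: int = 0) -> tuple[float, float]:
    """Mantel correlation between two labelled distance matrices.

    Pearson r over off-diagonal entries; the p-value co-permutes rows and
    columns of the second matrix.  With <= 7 labels all permutations are
    enumerated (exact p = proportion of permutations with |r| >= |r_obs|);
    otherwise ``perms`` random permutations with the add-one correction.
    """
    if list(d1.index) != list(d1.columns) or list(d2.index) != list(d2.columns):
        raise ValueError("distance matrices must be square and labelled")
    if list(d1.index) != list(d2.index):
        raise ValueError("distance matrices have different labels")
    x = d1.to_numpy(dtype=float)
    y = d2.to_numpy(dtype=float)
    if not (np.allclose(x, x.T) and np.allclose(y, y.T)):
        raise ValueError("distance matrices must be symmetric")
    n = x.shape[0]
    tri = np.triu_indices(n, k=1)

    def corr(perm):
        yp = y[np.ix_(perm, perm)]
        return sps.pearsonr(x[tri], yp[tri])[0]

    r_obs = corr(np.arange(n))
    if n <= 7:
        rs = np.array([corr(np.array(p)) for p in
                       itertools.permutations(range(n))])
        p = float((np.abs(rs) >= np.abs(r_obs) - 1e-12).mean())
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(perms):
            count += abs(corr(rng.permutation(n))) >= abs(r_obs) - 1e-12
        p = (count + 1) / (perms + 1)
    return float(r_obs), p


def ols_report(x, y) -> dict:
    """Ordinary least squares of y on x with the t-test p-value on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return {"slope": res.slope, "intercept": res.intercept,
            "r": res.rvalue, "r2": res.rvalue**2, "p": res.pvalue,
            "stderr": res.stderr, "n": int(x.size)}


def ibd_and_gradient_report(gm: GenotypeMatrix, popmap: PopulationMap, *,
                            div: DiversitySummary | None = None,
                            geo_dist: pd.DataFrame | None = None,
                            n_boot: int = 200, mantel_perms: int = 10_000,
                            seed: int = 0) -> dict:
    """Distance-gradient regressions and the FST isolation-by-distance test.

    Fits He ~ distance, beta_ST ~ distance, FST(vs the most-source-proximal
    population) ~ distance and Tajima's D ~ distance, plus a Mantel test of
    pairwise FST against geographic distance (pairwise |distance_km|
    difference unless a matrix is supplied).  Returns a tidy table and the
    underlying per-population frame.
    """
    if div is None:
        div = diversity(gm, popmap)
    per_pop = div.per_population.copy()
    per_pop["distance_km"] = [popmap.distance_of(p) for p in per_pop["population"]]
    beta = (div.beta_st if div.beta_st is not None
            else beta_st(gm, popmap, n_boot=n_boot, seed=seed))
    per_pop = per_pop.merge(beta[["population", "beta"]], on="population")
    source = per_pop.loc[per_pop["distance_km"].idxmin(), "population"]
    fsts = {p: (0.0 if p == source else wc_fst(gm, popmap, source, p))
            for p in per_pop["population"]}
    per_pop["fst_vs_source"] = per_pop["population"].map(fsts)
    rows = []
    for resp in ("He", "beta", "fst_vs_source", "tajimas_d"):
        sub = per_pop if resp != "fst_vs_source" else \
            per_pop[per_pop["population"] != source]
        try:
            rep = ols_report(sub["distance_km"], sub[resp])
        except ValueError as exc:
            rep = {"slope": np.nan, "intercept": np.nan, "r": np.nan,
                   "r2": np.nan, "p": np.nan, "n": int(len(sub))}
            warnings.warn(f"regression {resp} ~ distance skipped: {exc}")
        rep["response"] = resp
        rows.append(rep)
    table = pd.DataFrame(rows)[["response", "slope", "intercept", "r", "r2",
                                "p", "n"]]
    fst_mat = fst_matrix(gm, popmap)
    if geo_dist is None:
        dist = per_pop.set_index("population")["distance_km"]
        labels = list(fst_mat.index)
        geo = np.abs(dist[labels].to_numpy()[:, None]
                     - dist[labels].to_numpy()[None, :])
        geo_dist = pd.DataFrame(geo, index=labels, columns=labels)
    r, p = mantel(fst_mat, geo_dist, perms=mantel_perms, seed=seed)
    return {"regressions": table, "per_population": per_pop,
            "mantel_fst_geo": {"r": r, "p": p}, "fst_matrix": fst_mat,
            "source_population": source}
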