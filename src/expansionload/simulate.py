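"""Synthetic data generators: two-population jSFS datasets, a serial-founder
range expansion with deleterious mutations, and outgroup panels.

The range expansion is a forward Wright-Fisher simulation of K demes in a
linear array.  Deme k is founded at generation k * dt_found by F founders
drawn from deme k-1 and then grows towards the carrying capacity N.  Each
generation applies, in order: stepping-stone migration between adjacent
demes, viability selection against derived alleles at deleterious loci
(fitness 1, 1-h*s, 1-s per locus, multiplicative across loci), and
Wright-Fisher reproduction with mutation.  Loci are biallelic; a derived
allele can only arise by mutation at a locus where it is currently absent
from the whole metapopulation (no recurrent origin while segregating, no
back mutation).  The ancestral allele is always the reference, so the
simulator provides exact truth for polarization and load bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .genotypes import GenotypeMatrix, PopulationMap
from .demography import DemographicParams, simulate_dataset

__all__ = ["TwoPopScenario", "gen_two_pop_dataset", "ExpansionSimConfig",
           "gen_range_expansion", "gen_outgroup_panel", "write_fixtures"]


# ---------------------------------------------------------------------------
# two-population coalescent datasets
# ---------------------------------------------------------------------------

@dataclass
class TwoPopScenario:
    """A known divergence truth plus sampling configuration."""

    params: DemographicParams
    n1: int = 16
    n2: int = 16
    n_loci: int = 1000
    n_sites: int = 20_000
    seed: int = 0

    def __post_init__(self):
        if self.n_loci <= 0 or self.n_sites <= 0:
            raise ValueError("n_loci and n_sites must be positive")


def gen_two_pop_dataset(scn: TwoPopScenario, *, n_genealogies: int = 5000,
                        folded: bool = False):
    """Observed jSFS drawn around the four-category mixture, with true labels.

    Loci are assigned to the (migration x Ne) heterogeneity categories
    multinomially with the product weights P(1-Q), (1-P)(1-Q), PQ, (1-P)Q;
    the observed spectrum is a multinomial draw of ``n_sites`` segregating
    sites from the realized category mixture.  Returns (JointSFS, labels).
    """
    return simulate_dataset(scn.params, scn.n1, scn.n2, n_sites=scn.n_sites,
                            n_loci=scn.n_loci, n_genealogies=n_genealogies,
                            seed=scn.seed, folded=folded, return_labels=True)


# ---------------------------------------------------------------------------
# forward range-expansion simulation
# ---------------------------------------------------------------------------

@dataclass
class ExpansionSimConfig:
    """Serial-founder expansion along a linear array of demes.

    Defaults are the desk-scale study conditions: 8 demes of 100 diploids,
    10 founders per new deme every 50 generations, weak stepping-stone
    migration, 1000 neutral + 1000 deleterious loci with additive selection
    s = 0.01 (h = 0.5), 600 generations of expansion after a 1000-generation
    (10 N) burn-in of the source deme.
    """

    n_demes: int = 8                 # K
    capacity: int = 100              # N diploids per deme
    founders: int = 10               # F
    dt_found: int = 50               # generations between founding events
    m_step: float = 0.01             # per-individual adjacent-deme migration
    l_neutral: int = 1000
    l_deleterious: int = 1000
    u: float = 1e-4                  # per-locus per-gamete mutation rate
    s: float = 0.01                  # selection against derived deleterious
    h: float = 0.5                   # dominance of the deleterious allele
    generations: int = 600           # expansion phase length G
    burn_in: int = 100               # source-deme settling before expansion
    n_ancestral: int = 2000          # ancestral pool size shaping initial SFS
    p_seg: float = 0.7               # fraction of loci polymorphic ancestrally
    growth_rate: float = 1.4         # per-generation logistic growth factor
    sample_size: int = 25            # diploids sampled per deme at the end
    seed: int = 0

    def __post_init__(self):
        if self.founders > self.capacity:
            raise ValueError("founders must not exceed deme capacity")
        if not (0 <= self.m_step <= 0.5):
            raise ValueError("m_step must lie in [0, 0.5]")
        if not (0 <= self.h <= 1):
            raise ValueError("h must lie in [0, 1]")
        if self.s < 0 or self.s >= 1:
            raise ValueError("s must lie in [0, 1)")
        if self.sample_size > self.capacity:
            raise ValueError("sample_size must not exceed deme capacity")
        if self.n_demes < 1 or self.capacity < 2:
            raise ValueError("need at least one deme of two individuals")


@njit(cache=True)
def _run_expansion(K, N, F, dt_found, m_step, L, del_idx, u, s, h,
                   G, burn_in, growth_rate, n_ancestral, p_seg,
                   seed):  # pragma: no cover - jit
    np.random.seed(seed)
    geno = np.zeros((K, N, L), np.int8)
    nxt = np.zeros((K, N, L), np.int8)
    size = np.zeros(K, np.int64)
    size_next = np.zeros(K, np.int64)
    # The source deme descends from a large ancestral population of size
    # n_ancestral: each locus is polymorphic in the ancestral pool with
    # probability p_seg, at a frequency drawn from the neutral stationary
    # density (proportional to 1/p) between 1/(2*n_ancestral) and 1/2, so
    # standing variation at the expansion onset is dominated by rare alleles.
    p_min = 1.0 / (2.0 * n_ancestral)
    log_span = np.log(0.5 / p_min)
    for l in range(L):
        if np.random.random() < p_seg:
            p = p_min * np.exp(np.random.random() * log_span)
            for ind in range(N):
                g = 0
                if np.random.random() < p:
                    g += 1
                if np.random.random() < p:
                    g += 1
                geno[0, ind, l] = g
    size[0] = N
    log1hs = np.log(1.0 - h * s) if h * s > 0 else 0.0
    log1s = np.log(1.0 - s) if s > 0 else 0.0
    w = np.empty(N, np.float64)
    cw = np.empty(N, np.float64)
    occupied = np.zeros(L, np.bool_)
    unocc = np.empty(L, np.int64)
    n_del = del_idx.size
    for gen in range(burn_in + G):
        t_exp = gen - burn_in
        # founding events
        if t_exp >= 0:
            for k in range(1, K):
                if t_exp == k * dt_found and size[k] == 0 and size[k - 1] > 0:
                    for f in range(F):
                        src = np.random.randint(size[k - 1])
                        for l in range(L):
                            geno[k, f, l] = geno[k - 1, src, l]
                    size[k] = F
        # stepping-stone migration: conservative pairwise swaps
        if m_step > 0.0:
            for k in range(K - 1):
                if size[k] > 0 and size[k + 1] > 0:
                    nmax = min(size[k], size[k + 1])
                    nm = np.random.binomial(nmax, m_step)
                    for _ in range(nm):
                        i1 = np.random.randint(size[k])
                        i2 = np.random.randint(size[k + 1])
                        for l in range(L):
                            tmp = geno[k, i1, l]
                            geno[k, i1, l] = geno[k + 1, i2, l]
                            geno[k + 1, i2, l] = tmp
        # loci currently devoid of the derived allele (mutable)
        for l in range(L):
            occupied[l] = False
        for k in range(K):
            for ind in range(size[k]):
                for l in range(L):
                    if geno[k, ind, l] > 0:
                        occupied[l] = True
        n_unocc = 0
        for l in range(L):
            if not occupied[l]:
                unocc[n_unocc] = l
                n_unocc += 1
        # selection + reproduction + mutation, deme by deme
        total_next = 0
        for k in range(K):
            if size[k] == 0:
                size_next[k] = 0
                continue
            sz = size[k]
            wsum = 0.0
            for ind in range(sz):
                lw = 0.0
                if s > 0.0:
                    for j in range(n_del):
                        g = geno[k, ind, del_idx[j]]
                        if g == 1:
                            lw += log1hs
                        elif g == 2:
                            lw += log1s
                w[ind] = np.exp(lw)
                wsum += w[ind]
            if wsum <= 0.0:
                return geno, size, k, gen  # extinct deme (all fitness zero)
            cum = 0.0
            for ind in range(sz):
                cum += w[ind]
                cw[ind] = cum
            if sz >= N:
                target = N
            else:
                target = int(round(sz * growth_rate))
                if target > N:
                    target = N
                if target < sz:
                    target = sz
            for off in range(target):
                r1 = np.random.random() * wsum
                r2 = np.random.random() * wsum
                p1 = np.searchsorted(cw[:sz], r1)
                p2 = np.searchsorted(cw[:sz], r2)
                if p1 >= sz:
                    p1 = sz - 1
                if p2 >= sz:
                    p2 = sz - 1
                for l in range(L):
                    g1 = geno[k, p1, l]
                    g2 = geno[k, p2, l]
                    al = 0
                    if g1 == 2:
                        al += 1
                    elif g1 == 1 and np.random.random() < 0.5:
                        al += 1
                    if g2 == 2:
                        al += 1
                    elif g2 == 1 and np.random.random() < 0.5:
                        al += 1
                    nxt[k, off, l] = al
            size_next[k] = target
            total_next += target
        # new mutations on offspring, only at currently empty loci
        if n_unocc > 0 and u > 0.0 and total_next > 0:
            nmut = np.random.poisson(2.0 * total_next * u * n_unocc)
        else:
            nmut = 0
        for _ in range(nmut):
            if n_unocc == 0:
                break
            pick = np.random.randint(n_unocc)
            l = unocc[pick]
            # choose a random offspring individual across demes
            tgt = np.random.randint(total_next)
            acc = 0
            for k in range(K):
                if size_next[k] == 0:
                    continue
                if tgt < acc + size_next[k]:
                    ind = tgt - acc
                    if nxt[k, ind, l] < 2:
                        nxt[k, ind, l] += 1
                        unocc[pick] = unocc[n_unocc - 1]
                        n_unocc -= 1
                    break
                acc += size_next[k]
        # swap generations
        for k in range(K):
            size[k] = size_next[k]
            for ind in range(size[k]):
                for l in range(L):
                    geno[k, ind, l] = nxt[k, ind, l]
    return geno, size, -1, -1


def gen_range_expansion(cfg: ExpansionSimConfig
                        ) -> tuple[GenotypeMatrix, pd.DataFrame, PopulationMap]:
    """Run the forward simulation and sample genotypes, truth and a popmap.

    Returns a GenotypeMatrix of ``sample_size`` diploids per extant deme, a
    site-annotation table (deleterious loci carry score -3.0 and class
    nonsynonymous, neutral loci 0.0/synonymous; the true ancestral allele is
    always the reference), and a population map with one population per deme
    at distance deme_index * 100 km.
    """
    L = cfg.l_neutral + cfg.l_deleterious
    del_idx = np.arange(cfg.l_neutral, L, dtype=np.int64)
    geno, size, bad_deme, bad_gen = _run_expansion(
        cfg.n_demes, cfg.capacity, cfg.founders, cfg.dt_found, cfg.m_step,
        L, del_idx, cfg.u, cfg.s, cfg.h, cfg.generations, cfg.burn_in,
        cfg.growth_rate, cfg.n_ancestral, cfg.p_seg, int(cfg.seed) % 2**31)
    if bad_deme >= 0:
        raise RuntimeError(f"deme {bad_deme} went extinct (zero total fitness) "
                           f"at generation {bad_gen} with seed {cfg.seed}")
    rng = np.random.default_rng(cfg.seed + 101)
    values, individuals, pop_rows = [], [], []
    for k in range(cfg.n_demes):
        if size[k] < cfg.sample_size:
            continue
        chosen = rng.choice(int(size[k]), size=cfg.sample_size, replace=False)
        for c, ind in enumerate(chosen):
            name = f"deme{k + 1}_ind{c + 1}"
            individuals.append(name)
            values.append(geno[k, ind].copy())
            pop_rows.append({"sample": name, "population": f"deme{k + 1}",
                             "region": f"region{k // 2 + 1}",
                             "lat": 40.0 + k, "lon": -125.0 + k,
                             "distance_km": 100.0 * k})
    values = np.array(values, dtype=np.int8)
    sites = pd.DataFrame({
        "chrom": "sim1",
        "pos": np.arange(1, L + 1),
        "locus": [f"locus{l + 1}" for l in range(L)],
        "ref": "A",
        "alt": "T",
        "mean_depth": np.nan,
    })
    annotations = pd.DataFrame({
        "chrom": "sim1",
        "pos": np.arange(1, L + 1),
        "functional_class": ["synonymous"] * cfg.l_neutral
                            + ["nonsynonymous"] * cfg.l_deleterious,
        "degeneracy": [4] * cfg.l_neutral + [0] * cfg.l_deleterious,
        "score": [0.0] * cfg.l_neutral + [-3.0] * cfg.l_deleterious,
        "ancestral": "ref",
    })
    gm = GenotypeMatrix(values, sites, individuals)
    popmap = PopulationMap(pd.DataFrame(pop_rows))
    return gm, annotations, popmap


# ---------------------------------------------------------------------------
# outgroup panel
# ---------------------------------------------------------------------------

def gen_outgroup_panel(sites: pd.DataFrame, *, error_rate: float = 0.0,
                       missing_rate: float = 0.0, seed: int = 0,
                       ancestral: pd.Series | np.ndarray | str = "ref"
                       ) -> pd.DataFrame:
    """Three-outgroup genotype table around a known ancestral state.

    Each outgroup column is, independently per site: missing ('NN') with
    probability ``missing_rate``; otherwise homozygous for the wrong (non-
    ancestral) focal allele with probability ``error_rate``; otherwise
    homozygous ancestral.
    """
    if not (0 <= error_rate < 1 and 0 <= missing_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if isinstance(ancestral, str):
        anc_is_ref = np.full(len(sites), ancestral == "ref")
    else:
        anc_is_ref = np.asarray(pd.Series(ancestral) == "ref")
    anc = np.where(anc_is_ref, sites["ref"], sites["alt"])
    wrong = np.where(anc_is_ref, sites["alt"], sites["ref"])
    out = {"chrom": sites["chrom"].to_numpy(), "pos": sites["pos"].to_numpy()}
    for og in ("og1", "og2", "og3"):
        u = rng.random(len(sites))
        v = rng.random(len(sites))
        col = np.where(u < missing_rate, "NN",
                       np.where(v < error_rate,
                                pd.Series(wrong) + pd.Series(wrong),
                                pd.Series(anc) + pd.Series(anc)))
        out[og] = col
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

_FIXTURE_GENES = {
    # name: (chrom, start(1-based), strand, CDS sequence written on + strand)
    "geneA": ("chr_cds", 11, "+", "ATGGCTGGATTAAGTCGATAG"),
    "geneB": ("chr_cds", 61, "-", "ATGCCTAAGTTCGAA"),  # as mRNA; genome holds revcomp
}


def write_cds_fixture(outdir) -> tuple[str, str]:
    """Tiny GFF3 + FASTA pair with one plus- and one minus-strand gene."""
    from pathlib import Path
    outdir = Path(outdir)
    chrom_len = 120
    seq = list("ACGT" * (chrom_len // 4))
    rc = str.maketrans("ACGT", "TGCA")
    for name, (chrom, start, strand, cds) in _FIXTURE_GENES.items():
        genomic = cds if strand == "+" else cds.translate(rc)[::-1]
        for i, base in enumerate(genomic):
            seq[start - 1 + i] = base
    fasta = outdir / "cds.fasta"
    gff = outdir / "cds.gff3"
    with open(fasta, "w") as fh:
        fh.write(">chr_cds\n" + "".join(seq) + "\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, (chrom, start, strand, cds) in _FIXTURE_GENES.items():
            end = start + len(cds) - 1
            fh.write(f"{chrom}\t.\tgene\t{start}\t{end}\t.\t{strand}\t."
                     f"\tID={name}\n")
            fh.write(f"{chrom}\t.\tmRNA\t{start}\t{end}\t.\t{strand}\t."
                     f"\tID={name}.t1;Parent={name}\n")
            fh.write(f"{chrom}\t.\tCDS\t{start}\t{end}\t.\t{strand}\t0"
                     f"\tID={name}.cds;Parent={name}.t1\n")
    return str(gff), str(fasta)


def write_fixtures(outdir, seed: int = 0) -> dict:
    """Deterministic fixture bundle: VCF, popmap, outgroups, scores, CDS pair."""
    from pathlib import Path

    from .vcfio import write_vcf, write_popmap, write_outgroups, write_scores

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = ExpansionSimConfig(n_demes=3, capacity=30, founders=8, dt_found=30,
                             l_neutral=40, l_deleterious=40, u=5e-4,
                             generations=90, burn_in=240, sample_size=10,
                             seed=seed)
    gm, ann, popmap = gen_range_expansion(cfg)
    rng = np.random.default_rng(seed + 7)
    gm.sites["mean_depth"] = rng.integers(8, 40, size=gm.n_sites).astype(float)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "popmap": outdir / "popmap.tsv",
        "outgroups": outdir / "outgroups.tsv",
        "scores": outdir / "scores.tsv",
    }
    write_vcf(gm, paths["vcf"])
    write_popmap(popmap, paths["popmap"])
    og = gen_outgroup_panel(gm.sites, error_rate=0.02, missing_rate=0.05,
                            seed=seed + 13)
    write_outgroups(og, paths["outgroups"])
    scores = ann[["chrom", "pos", "score"]]
    write_scores(scores, paths["scores"])
    gff, fasta = write_cds_fixture(outdir)
    paths["gff"] = gff
    paths["fasta"] = fasta
    paths["annotations"] = outdir / "annotations.tsv"
    ann.to_csv(paths["annotations"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
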