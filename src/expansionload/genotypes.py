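"""Genotype matrix, population map, and the SNP/individual filter cascade.

Genotypes are stored as ALT (or derived, after polarization) allele-copy
counts in {0, 1, 2}, with missing calls encoded by the sentinel ``MISSING``
(never 0).  The filter cascade reproduces a reduced-representation (GBS)
quality pipeline: an initial per-site stage (call rate >= 60%, mean depth
>= 7, observed heterozygosity <= 0.60), an individual stage (drop
individuals with > 5% missing data), and a final per-site stage (call rate
>= 95%), applied in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

__all__ = ["MISSING", "GenotypeMatrix", "PopulationMap", "FilterReport",
           "filter_sites", "filter_individuals", "thin_one_snp_per_locus"]

MISSING: int = -9

SITE_COLUMNS = ["chrom", "pos", "locus", "ref", "alt", "mean_depth"]


@dataclass
class GenotypeMatrix:
    """Individuals x sites ALT allele-copy counts with per-site metadata."""

    values: np.ndarray                 # (n_individuals, n_sites) int8
    sites: pd.DataFrame                # columns SITE_COLUMNS
    individuals: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x sites)")
        ok = np.isin(self.values, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.values[~ok])
            raise ValueError(f"invalid genotype codes {bad}; expected 0/1/2/MISSING")
        self.sites = self.sites.reset_index(drop=True)
        missing_cols = set(SITE_COLUMNS) - set(self.sites.columns)
        if missing_cols:
            raise ValueError(f"site table lacks columns {sorted(missing_cols)}")
        if len(self.sites) != self.values.shape[1]:
            raise ValueError("site table and genotype matrix disagree on site count")
        if len(self.individuals) != self.values.shape[0]:
            raise ValueError("individual labels and genotype matrix disagree")
        if self.sites.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in site table")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def called(self) -> np.ndarray:
        return self.values != MISSING

    def site_call_rate(self) -> np.ndarray:
        return self.called().mean(axis=0)

    def site_het_obs(self) -> np.ndarray:
        """Observed heterozygosity per site among called genotypes."""
        called = self.called()
        het = (self.values == 1) & called
        with np.errstate(invalid="ignore"):
            return np.where(called.sum(0) > 0, het.sum(0) / called.sum(0), np.nan)

    def individual_missing_rate(self) -> np.ndarray:
        return 1.0 - self.called().mean(axis=1)

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.values[:, index],
                             self.sites.iloc[index], list(self.individuals))

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.values[index],
                             self.sites, [self.individuals[i] for i in index])

    def allele_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(ALT copies, called copies) per site, optionally over a row subset."""
        v = self.values if rows is None else self.values[rows]
        called = v != MISSING
        alt = np.where(called, v, 0).sum(axis=0)
        return alt.astype(np.int64), (2 * called.sum(axis=0)).astype(np.int64)


POPMAP_COLUMNS = ["sample", "population", "region", "lat", "lon", "distance_km"]


@dataclass
class PopulationMap:
    """sample -> population / region assignment with distance from the source."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(POPMAP_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"population map lacks columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate samples in population map")
        if (self.table["distance_km"] < 0).any():
            raise ValueError("distance_km must be >= 0")

    def validate_against(self, gm: GenotypeMatrix) -> None:
        absent = set(gm.individuals) - set(self.table["sample"])
        if absent:
            raise ValueError(f"{len(absent)} genotyped individuals missing from "
                             f"population map, e.g. {sorted(absent)[:3]}")

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.table["region"]))

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample"], self.table["population"]))

    def region_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample"], self.table["region"]))

    def members(self, population: str, individuals: list[str]) -> np.ndarray:
        pop_of = self.population_of()
        return np.array([i for i, ind in enumerate(individuals)
                         if pop_of.get(ind) == population], dtype=int)

    def distance_of(self, population: str) -> float:
        rows = self.table[self.table["population"] == population]
        return float(rows["distance_km"].iloc[0])


@dataclass
class FilterReport:
    stage: str
    n_in: int
    n_out: int
    removed: dict[str, int] = field(default_factory=dict)


def filter_sites(gm: GenotypeMatrix, stage: str = "initial",
                 *, call_rate_initial: float = 0.60, min_mean_depth: float = 7.0,
                 max_het_obs: float = 0.60, call_rate_final: float = 0.95
                 ) -> tuple[GenotypeMatrix, FilterReport]:
    """Per-site quality filters.

    ``stage='initial'``: drop sites genotyped in less than 60% of
    individuals, with mean depth below 7, or with observed heterozygosity
    above 0.60 (a site at exactly 0.60 is retained).  ``stage='final'``:
    keep sites genotyped in at least 95% of individuals.  The depth rule is
    skipped with a warning when depths are absent.
    """
    if stage not in ("initial", "final"):
        raise ValueError(f"unknown filter stage {stage!r}")
    keep = np.ones(gm.n_sites, dtype=bool)
    removed: dict[str, int] = {}
    if stage == "initial":
        cr = gm.site_call_rate()
        fail = cr < call_rate_initial
        removed["call_rate"] = int((keep & fail).sum())
        keep &= ~fail
        depth = gm.sites["mean_depth"].to_numpy(dtype=float)
        if np.isnan(depth).all():
            warnings.warn("mean depth absent from site table; depth filter skipped")
        else:
            fail = np.nan_to_num(depth, nan=np.inf) < min_mean_depth
            removed["mean_depth"] = int((keep & fail).sum())
            keep &= ~fail
        ho = gm.site_het_obs()
        fail = np.nan_to_num(ho, nan=0.0) > max_het_obs
        removed["het_obs"] = int((keep & fail).sum())
        keep &= ~fail
    else:
        cr = gm.site_call_rate()
        fail = cr < call_rate_final
        removed["call_rate"] = int(fail.sum())
        keep &= ~fail
    out = gm.take_sites(np.flatnonzero(keep))
    return out, FilterReport(stage, gm.n_sites, out.n_sites, removed)


def filter_individuals(gm: GenotypeMatrix, *, max_missing: float = 0.05
                       ) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop individuals with strictly more than ``max_missing`` missing data."""
    n_miss = (~gm.called()).sum(axis=1)
    # integer comparison avoids float-rounding at the exact boundary (k/n == q)
    keep = np.flatnonzero(n_miss <= np.floor(max_missing * gm.n_sites + 1e-9))
    if keep.size == 0:
        raise ValueError("all individuals removed by the missing-data filter; "
                         "review the max_missing threshold")
    out = gm.take_individuals(keep)
    return out, FilterReport("individuals", gm.n_individuals, out.n_individuals,
                             {"missing_rate": gm.n_individuals - out.n_individuals})


def thin_one_snp_per_locus(gm: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Retain one uniformly chosen SNP per locus (seeded, reproducible)."""
    loci = gm.sites["locus"]
    if loci.isna().any():
        raise ValueError("locus ids missing; cannot thin per locus")
    rng = np.random.default_rng(seed)
    chosen = []
    for _, idx in loci.groupby(loci, sort=True).groups.items():
        idx = np.asarray(idx)
        chosen.append(int(rng.choice(idx)))
    chosen.sort()
    return gm.take_sites(chosen)
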