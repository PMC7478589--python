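"""Joint and one-dimensional site-frequency spectra.

The joint SFS (jSFS) is the (n1+1) x (n2+1) grid of counts of variants whose
derived (or minor, when folded) allele occurs i times in a sample of n1
haploid copies from population 1 and j times in n2 copies from population 2.
The monomorphic corners (0, 0) and (n1, n2) carry no information about
segregating variation and are always masked.

Missing genotypes are handled by hypergeometric projection: a site with c >= n
called copies contributes fractional weight hypergeom(i; c, d, n) to entry i,
which preserves the expected frequency exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

__all__ = ["JointSFS", "project_counts", "fold_1d", "jsfs_from_genotypes",
           "sfs_1d"]


@lru_cache(maxsize=4096)
def _projection_weights(n_called: int, n_derived: int, n_proj: int) -> tuple:
    """P(i derived among n_proj drawn without replacement | n_derived of n_called)."""
    i = np.arange(n_proj + 1)
    return tuple(hypergeom.pmf(i, n_called, n_derived, n_proj))


def project_counts(n_called: int, n_derived: int, n_proj: int) -> np.ndarray:
    """Hypergeometric down-projection of a single site's allele count."""
    if n_proj > n_called:
        raise ValueError("cannot project up: n_proj > n_called")
    return np.asarray(_projection_weights(int(n_called), int(n_derived), int(n_proj)))


@dataclass
class JointSFS:
    counts: np.ndarray
    folded: bool = False
    mask: np.ndarray = field(default=None)  # True where excluded

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("jSFS counts must be a 2-D grid")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("jSFS counts must be finite and non-negative")
        if self.mask is None:
            self.mask = self.default_mask(self.n1, self.n2, self.folded)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape mismatch")
        self.counts = np.where(self.mask, 0.0, self.counts)

    @staticmethod
    def default_mask(n1: int, n2: int, folded: bool) -> np.ndarray:
        mask = np.zeros((n1 + 1, n2 + 1), dtype=bool)
        mask[0, 0] = True
        mask[n1, n2] = True
        if folded:
            i = np.arange(n1 + 1)[:, None]
            j = np.arange(n2 + 1)[None, :]
            mask |= (2 * (i + j) > n1 + n2)
        return mask

    @property
    def n1(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.counts.shape[1] - 1

    def total(self) -> float:
        return float(self.counts[~self.mask].sum())

    def fold(self) -> "JointSFS":
        """Fold onto minor-allele counts (total count i + j <= (n1+n2)/2).

        Cells on the hinge 2(i+j) == n1+n2 receive half the summed mass of the
        cell and its complement, so folding is idempotent and mass-preserving.
        """
        if self.folded:
            return JointSFS(self.counts.copy(), folded=True)
        c = self.counts + self.counts[::-1, ::-1]
        i = np.arange(self.n1 + 1)[:, None]
        j = np.arange(self.n2 + 1)[None, :]
        tot = 2 * (i + j)
        c = np.where(tot == self.n1 + self.n2, c / 2.0, c)
        c = np.where(tot > self.n1 + self.n2, 0.0, c)
        return JointSFS(c, folded=True)

    def marginal(self, axis: int) -> np.ndarray:
        return np.where(self.mask, 0.0, self.counts).sum(axis=1 - axis)

    def pooled(self) -> np.ndarray:
        """1-D spectrum of total (i + j) counts over unmasked cells."""
        out = np.zeros(self.n1 + self.n2 + 1)
        c = np.where(self.mask, 0.0, self.counts)
        for i in range(self.n1 + 1):
            for j in range(self.n2 + 1):
                out[i + j] += c[i, j]
        return out

    # --- plain-text round trip (header: "n1 n2 folded") ---
    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n1} {self.n2} {int(self.folded)}\n")
            for row in self.counts:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def from_text(cls, path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 3:
                raise ValueError(f"bad jSFS header in {path}")
            n1, n2, folded = int(header[0]), int(header[1]), bool(int(header[2]))
            counts = np.loadtxt(fh, ndmin=2)
        if counts.shape != (n1 + 1, n2 + 1):
            raise ValueError(f"jSFS grid shape {counts.shape} does not match header")
        return cls(counts, folded=folded)


def jsfs_from_genotypes(gm, popmap, pop1: str, pop2: str, *,
                        polarized: bool = False,
                        projection: tuple[int, int] | None = None) -> JointSFS:
    """Build the joint SFS of two populations from a genotype matrix.

    Allele counts are the ALT copies (assumed pre-oriented to the derived
    allele when ``polarized=True``; otherwise the spectrum is folded).  Sites
    are down-projected hypergeometrically to ``projection`` haploid sample
    sizes; sites with fewer called copies than the projection are skipped
    (their number is logged).  No minor-allele-frequency filter is ever
    applied and singletons are kept.
    """
    import logging

    rows1 = popmap.members(pop1, gm.individuals)
    rows2 = popmap.members(pop2, gm.individuals)
    if rows1.size == 0 or rows2.size == 0:
        raise ValueError(f"empty population among ({pop1!r}, {pop2!r})")
    if np.intersect1d(rows1, rows2).size:
        raise ValueError("populations overlap")
    d1, c1 = gm.allele_counts(rows1)
    d2, c2 = gm.allele_counts(rows2)
    if projection is None:
        n1, n2 = 2 * rows1.size, 2 * rows2.size
    else:
        n1, n2 = projection
        if n1 > 2 * rows1.size or n2 > 2 * rows2.size:
            raise ValueError("projection exceeds available haploid sample size")
    counts = np.zeros((n1 + 1, n2 + 1))
    n_skipped = 0
    for j in range(gm.n_sites):
        if c1[j] < n1 or c2[j] < n2:
            n_skipped += 1
            continue
        w1 = project_counts(c1[j], d1[j], n1)
        w2 = project_counts(c2[j], d2[j], n2)
        counts += np.outer(w1, w2)
    if n_skipped:
        logging.getLogger(__name__).info(
            "jsfs_from_genotypes: %d sites skipped (insufficient calls for "
            "projection)", n_skipped)
    out = JointSFS(counts, folded=False)
    return out if polarized else out.fold()


def sfs_1d(gm, popmap, pop: str, *, projection: int | None = None,
           polarized: bool = False) -> np.ndarray:
    """One-population SFS with hypergeometric projection (folded if not polarized)."""
    rows = popmap.members(pop, gm.individuals)
    if rows.size == 0:
        raise ValueError(f"empty population {pop!r}")
    d, c = gm.allele_counts(rows)
    n = 2 * rows.size if projection is None else projection
    xi = np.zeros(n + 1)
    for j in range(gm.n_sites):
        if c[j] < n:
            continue
        xi += project_counts(c[j], d[j], n)
    xi[0] = xi[n] = 0.0
    return xi if polarized else fold_1d(xi)


def fold_1d(xi: np.ndarray) -> np.ndarray:
    """Fold a 1-D unfolded spectrum onto minor-allele counts."""
    xi = np.asarray(xi, dtype=float)
    n = len(xi) - 1
    out = np.zeros_like(xi)
    for i in range(1, n):
        if 2 * i < n:
            out[i] = xi[i] + xi[n - i]
        elif 2 * i == n:
            out[i] = xi[i]
    return out
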