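"""Readers and writers for the standard input formats.

VCF parsing is delegated to cyvcf2/htslib; everything else (population map,
outgroup genotype table, deleteriousness score table, jSFS grid) is plain
TSV/text with documented headers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap, POPMAP_COLUMNS

__all__ = ["read_vcf", "write_vcf", "read_popmap", "write_popmap",
           "read_outgroups", "write_outgroups", "read_scores", "write_scores"]


def _locate_malformed_line(path) -> str:
    """Best-effort diagnosis: first data line with a wrong column count."""
    try:
        n_cols = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith("##"):
                    continue
                n = len(line.rstrip("\n").split("\t"))
                if line.startswith("#CHROM"):
                    n_cols = n
                    continue
                if n_cols is not None and n != n_cols:
                    return f"line {lineno} has {n} columns, expected {n_cols}"
    except OSError:
        pass
    return "location unknown"


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into ALT allele-copy counts.

    './.' becomes MISSING; per-site mean depth is taken from the FORMAT DP
    field when present (NaN otherwise).  The locus id is read from the INFO
    field ``LOC`` when present, then from the ID column, falling back to
    ``chrom:pos``.  Multi-allelic records raise (split them upstream).
    """
    from cyvcf2 import VCF
    try:
        vcf = VCF(str(path))
        individuals = list(vcf.samples)
        rows, meta = [], []
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        code = np.array([0, 1, MISSING, 2], dtype=np.int8)
        for v in vcf:
            if len(v.ALT) != 1:
                raise ValueError(
                    f"multi-allelic record at {v.CHROM}:{v.POS}; pre-split the VCF")
            gt = code[np.asarray(v.gt_types)]
            depth = np.nan
            try:
                d = v.format("DP")
            except Exception:
                d = None
            if d is not None:
                d = np.asarray(d, dtype=float).ravel()
                d = d[d >= 0]
                if d.size:
                    depth = float(d.mean())
            locus = v.INFO.get("LOC")
            if locus is None:
                locus = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
            rows.append(gt)
            meta.append((v.CHROM, v.POS, str(locus), v.REF, v.ALT[0], depth))
    except ValueError:
        raise
    except Exception as exc:  # htslib parse failure
        raise ValueError(f"malformed VCF {path} ({_locate_malformed_line(path)}): "
                         f"{exc}") from exc
    sites = pd.DataFrame(meta, columns=["chrom", "pos", "locus", "ref", "alt",
                                        "mean_depth"])
    values = (np.array(rows, dtype=np.int8).T if rows
              else np.empty((len(individuals), 0), dtype=np.int8))
    return GenotypeMatrix(values, sites, individuals)


def write_vcf(gm: GenotypeMatrix, path, *, depth_as_int: bool = True) -> None:
    """Write a minimal VCF v4.2 with GT (and DP when depth is known)."""
    has_depth = not gm.sites["mean_depth"].isna().all()
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(gm.sites["chrom"]):
            length = int(gm.sites.loc[gm.sites["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write('##INFO=<ID=LOC,Number=1,Type=String,Description="GBS locus id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individuals) + "\n")
        fmt = "GT:DP" if has_depth else "GT"
        for j, site in gm.sites.iterrows():
            calls = []
            depth = site["mean_depth"]
            dp = (str(int(round(depth))) if has_depth and np.isfinite(depth) else ".")
            for i in range(gm.n_individuals):
                g = gt_str[int(gm.values[i, j])]
                calls.append(f"{g}:{dp}" if has_depth else g)
            fh.write(f"{site['chrom']}\t{site['pos']}\t.\t{site['ref']}\t"
                     f"{site['alt']}\t.\tPASS\tLOC={site['locus']}\t{fmt}\t"
                     + "\t".join(calls) + "\n")


def read_popmap(path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t")
    return PopulationMap(df)


def write_popmap(popmap: PopulationMap, path) -> None:
    popmap.table[POPMAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_outgroups(path) -> pd.DataFrame:
    """Outgroup genotype table: chrom, pos, og1..og3 as 'AA'/'AC'/'NN'."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = {"chrom", "pos", "og1", "og2", "og3"}
    if not expected <= set(df.columns):
        raise ValueError(f"outgroup table lacks columns {sorted(expected - set(df.columns))}")
    return df


def write_outgroups(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "og1", "og2", "og3"]].to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    """Deleteriousness score table: chrom, pos, score."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos", "score"} <= set(df.columns):
        raise ValueError("score table needs columns chrom, pos, score")
    return df


def write_scores(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "score"]].to_csv(path, sep="\t", index=False)
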