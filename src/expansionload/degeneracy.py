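"""Codon degeneracy and functional classification of SNPs inside CDS.

For a site inside an annotated CDS the codon is reconstructed from the
spliced coding sequence (strand-aware), the degeneracy of its position is
computed under the standard genetic code (0-, 2- or 4-fold; 3-fold Ile sites
are conservatively treated as 2-fold), and the ref->alt substitution is
classed synonymous or nonsynonymous by translating both codons.  Sites
outside any CDS are classed noncoding.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

__all__ = ["CdsIndex", "codon_degeneracy", "annotate_sites"]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = "ACGT"


def _translate(codon: str) -> str:
    codon = codon.upper()
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table.get(codon, "X")


@dataclass
class _Transcript:
    chrom: str
    strand: str
    segments: list  # [(start, end)] 1-based inclusive, genome order


class CdsIndex:
    """CDS annotation (GFF3) plus genome (FASTA) lookup for codon context."""

    def __init__(self, gff3_path, fasta_path):
        self.sequences = _read_fasta(fasta_path)
        self.transcripts = _read_cds_gff3(gff3_path)

    def locate(self, chrom: str, pos: int):
        """(transcript, offset in spliced CDS) for a genomic site, or None."""
        for tx in self.transcripts.values():
            if tx.chrom != chrom:
                continue
            offset = 0
            for start, end in tx.segments:
                if start <= pos <= end:
                    within = pos - start + offset
                    length = sum(e - s + 1 for s, e in tx.segments)
                    if tx.strand == "-":
                        within = length - 1 - within
                    return tx, within
                offset += end - start + 1
        return None

    def spliced_cds(self, tx: _Transcript) -> str:
        seq = "".join(self.sequences[tx.chrom][s - 1:e] for s, e in tx.segments)
        if tx.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        return seq


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _read_cds_gff3(path) -> dict[str, _Transcript]:
    transcripts: dict[str, _Transcript] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "CDS":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = parts
            parent = None
            for item in attrs.split(";"):
                if item.startswith("Parent="):
                    parent = item[len("Parent="):]
                elif parent is None and item.startswith("ID="):
                    parent = item[len("ID="):]
            if parent is None:
                parent = f"cds_{chrom}_{start}"
            tx = transcripts.setdefault(parent, _Transcript(chrom, strand, []))
            if tx.chrom != chrom or tx.strand != strand:
                raise ValueError(f"inconsistent CDS segments for {parent}")
            tx.segments.append((int(start), int(end)))
    for name, tx in transcripts.items():
        tx.segments.sort()
    return transcripts


def codon_degeneracy(index: CdsIndex, chrom: str, pos: int, ref: str, alt: str
                     ) -> tuple[int | None, str]:
    """(degeneracy in {0, 2, 4} or None, functional class) of a substitution.

    Degeneracy counts how many of the four bases at the codon position leave
    the amino acid unchanged: 4 -> 4-fold, 2 or 3 -> 2-fold, 1 -> 0-fold.
    The class is synonymous/nonsynonymous from translating the ref and alt
    codons; outside CDS it is noncoding.  A CDS whose spliced length is not
    a multiple of three raises, naming the transcript.
    """
    hit = None
    for name, tx in index.transcripts.items():
        if tx.chrom != chrom:
            continue
        for start, end in tx.segments:
            if start <= pos <= end:
                hit = name
                break
        if hit:
            break
    if hit is None:
        return None, "noncoding"
    tx = index.transcripts[hit]
    cds = index.spliced_cds(tx)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length of {hit} ({len(cds)}) is not a multiple of 3")
    _, within = index.locate(chrom, pos)
    codon_i, codon_pos = divmod(within, 3)
    codon = cds[3 * codon_i:3 * codon_i + 3]
    strand_ref = ref.upper() if tx.strand == "+" else ref.upper().translate(_COMPLEMENT)
    strand_alt = alt.upper() if tx.strand == "+" else alt.upper().translate(_COMPLEMENT)
    if codon[codon_pos] != strand_ref:
        raise ValueError(f"reference allele {ref} does not match CDS base "
                         f"{codon[codon_pos]} at {chrom}:{pos} in {hit}")
    aa_ref = _translate(codon)
    n_same = sum(_translate(codon[:codon_pos] + b + codon[codon_pos + 1:]) == aa_ref
                 for b in _BASES)
    degeneracy = {1: 0, 2: 2, 3: 2, 4: 4}[n_same]
    alt_codon = codon[:codon_pos] + strand_alt + codon[codon_pos + 1:]
    klass = "synonymous" if _translate(alt_codon) == aa_ref else "nonsynonymous"
    return degeneracy, klass


def annotate_sites(index: CdsIndex, sites) -> "pd.DataFrame":
    """Degeneracy/class annotation for a site table (chrom, pos, ref, alt)."""
    import pandas as pd
    rows = []
    for _, site in sites.iterrows():
        deg, klass = codon_degeneracy(index, site["chrom"], int(site["pos"]),
                                      site["ref"], site["alt"])
        rows.append({"chrom": site["chrom"], "pos": int(site["pos"]),
                     "degeneracy": deg, "functional_class": klass})
    return pd.DataFrame(rows)
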