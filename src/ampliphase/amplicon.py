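"""Amplicon coordinate system, SNP catalog and reference sequence.

The pipeline operates on a single PCR amplicon of the GSTA1 proximal
promoter: a 1336-bp product mapped to GRCh38 chr6:52803791-52805125 that
contains six biallelic SNPs whose combinations define the promoter
haplotypes (*A1, *A2, *B1a, *B1b).  SNPs carry two coordinates: the
promoter-relative position used in their conventional names (e.g.
rs3957356-52 sits at -52) and a 0-based offset within the amplicon.  The
published product does not include the primer/TSS coordinates needed to
anchor the promoter scale onto the amplicon exactly, so the default offset
map is a rigid translation placing every SNP at least 120 bp from either
end; it is configurable through the SNP-catalog TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Amplicon length in bp.  The mapped genomic span (1-based inclusive
#: 52803791-52805125) covers 1335 bases while the product is described as
#: 1336 bp; the product length is authoritative for simulation.
AMPLICON_LENGTH = 1336
GENOMIC_CONTIG = "chr6"
GENOMIC_START = 52803791
GENOMIC_END = 52805125

#: Rigid translation from promoter-relative position to amplicon offset:
#: offset = promoter_pos + 1142 + MARGIN, leaving >=120 bp flanks.
OFFSET_MARGIN = 120

_BASES = "ACGT"


@dataclass(frozen=True)
class SnpDef:
    """One catalogued biallelic SNP.

    ``promoter_pos`` is the (negative) promoter-relative coordinate that
    appears in the SNP's conventional name; ``amplicon_offset`` is 0-based
    within the amplicon sequence.
    """

    snp_id: str
    promoter_pos: int
    amplicon_offset: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt allele are equal")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in _BASES:
                raise ValueError(f"{self.snp_id}: invalid allele {allele!r}")
        if self.amplicon_offset < 0:
            raise ValueError(f"{self.snp_id}: negative amplicon offset")


def _default_snps() -> tuple[SnpDef, ...]:
    # (snp_id, promoter_pos, ref, alt); ref alleles form the *A1 haplotype.
    raw = [
        ("rs3957356-52", -52, "G", "A"),
        ("rs3957357-69", -69, "C", "T"),
        ("rs11964968-513", -513, "A", "G"),
        ("rs4715332-567", -567, "T", "G"),
        ("rs4715333-631", -631, "T", "G"),
        ("rs58912740-1142", -1142, "C", "G"),
    ]
    snps = [
        SnpDef(sid, pos, pos + 1142 + OFFSET_MARGIN, ref, alt)
        for sid, pos, ref, alt in raw
    ]
    return tuple(sorted(snps, key=lambda s: s.amplicon_offset))


#: The six catalogued promoter SNPs, sorted by amplicon offset.
DEFAULT_SNPS: tuple[SnpDef, ...] = _default_snps()

#: Canonical catalog (= haplotype string) order of SNP ids.
SNP_IDS: tuple[str, ...] = tuple(s.snp_id for s in DEFAULT_SNPS)


@dataclass(frozen=True)
class AmpliconReference:
    """Reference sequence plus SNP catalog for one amplicon."""

    name: str
    sequence: str
    snps: tuple[SnpDef, ...]
    genomic_contig: str = GENOMIC_CONTIG
    genomic_start: int = GENOMIC_START
    genomic_end: int = GENOMIC_END

    def __post_init__(self) -> None:
        offsets = [s.amplicon_offset for s in self.snps]
        if offsets != sorted(set(offsets)):
            raise ValueError("SNP offsets must be strictly increasing")
        ids = [s.snp_id for s in self.snps]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate snp_id in catalog")
        for snp in self.snps:
            if snp.amplicon_offset >= len(self.sequence):
                raise ValueError(f"{snp.snp_id}: offset beyond amplicon end")
            base = self.sequence[snp.amplicon_offset]
            if base != snp.ref_allele:
                raise ValueError(
                    f"{snp.snp_id}: reference base {base} != ref allele "
                    f"{snp.ref_allele} at offset {snp.amplicon_offset}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(s.snp_id for s in self.snps)

    @property
    def snp_offsets(self) -> np.ndarray:
        return np.array([s.amplicon_offset for s in self.snps], dtype=np.int64)

    def snp(self, snp_id: str) -> SnpDef:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    def haplotype_alleles(self, which: str) -> tuple[str, ...]:
        """Alleles, in catalog order, of the all-ref ('ref') or all-alt
        ('alt') haplotype."""
        if which == "ref":
            return tuple(s.ref_allele for s in self.snps)
        if which == "alt":
            return tuple(s.alt_allele for s in self.snps)
        raise ValueError(which)


def build_default_reference(seed: int) -> AmpliconReference:
    """Build a reproducible random 1336-bp reference carrying the six
    catalogued SNPs (reference alleles planted at their offsets).

    The true promoter sequence is not bundled; for every operation in the
    pipeline only the SNP alleles matter, so a random background with the
    catalogued alleles planted is an exact stand-in (synthetic sequence).
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(list(_BASES), size=AMPLICON_LENGTH)
    for snp in DEFAULT_SNPS:
        seq[snp.amplicon_offset] = snp.ref_allele
    return AmpliconReference(
        name="GSTA1_promoter_amplicon",
        sequence="".join(seq),
        snps=DEFAULT_SNPS,
    )


def pairwise_distance(a: SnpDef, b: SnpDef) -> int:
    """Distance in bp between two catalogued SNPs.

    Computed from the promoter-relative labels; because the offset map is a
    rigid translation this equals the amplicon-offset distance.
    """
    return abs(a.promoter_pos - b.promoter_pos)


# ---------------------------------------------------------------------------
# FASTA / TSV I/O


def write_fasta(reference: AmpliconReference, path: str | Path) -> None:
    record = SeqRecord(
        Seq(reference.sequence),
        id=reference.name,
        description=(
            f"{reference.genomic_contig}:{reference.genomic_start}-"
            f"{reference.genomic_end}"
        ),
    )
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path: str | Path, snps: tuple[SnpDef, ...] | None = None) -> AmpliconReference:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record")
    rec = records[0]
    return AmpliconReference(
        name=rec.id,
        sequence=str(rec.seq).upper(),
        snps=DEFAULT_SNPS if snps is None else snps,
    )


_CATALOG_COLUMNS = ("snp_id", "promoter_pos", "amplicon_offset", "ref", "alt")


def write_snp_catalog(snps: tuple[SnpDef, ...], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for s in snps:
            fh.write(
                f"{s.snp_id}\t{s.promoter_pos}\t{s.amplicon_offset}"
                f"\t{s.ref_allele}\t{s.alt_allele}\n"
            )


def read_snp_catalog(path: str | Path) -> tuple[SnpDef, ...]:
    snps = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _CATALOG_COLUMNS:
            raise ValueError(f"{path}: bad catalog header {header}")
        for line in fh:
            if not line.strip():
                continue
            sid, pos, off, ref, alt = line.rstrip("\n").split("\t")
            snps.append(SnpDef(sid, int(pos), int(off), ref, alt))
    return tuple(sorted(snps, key=lambda s: s.amplicon_offset))
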