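"""GSTA1 promoter star-allele naming.

The four haplotypes distinguishable from the six catalogued promoter SNPs
are *A1 (all reference alleles), *A2 (alternate at rs4715333-631), *B1a
(alternate everywhere except rs11964968-513) and *B1b (alternate at all
six sites).  Haplotype allele strings are ordered like the SNP catalog
(ascending amplicon offset).  Rarer haplotypes (e.g. *A3, *B2) are not
distinguishable from the data modelled here and are not in the default
table; unknown combinations report "unassigned".  The table is
user-extensible via TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from .amplicon import DEFAULT_SNPS, SNP_IDS, SnpDef

Haplotype = tuple[str, ...]
StarTable = dict[str, Haplotype]


def _build_default_table() -> StarTable:
    ref = tuple(s.ref_allele for s in DEFAULT_SNPS)
    alt = tuple(s.alt_allele for s in DEFAULT_SNPS)

    def mix(alt_at: set[str]) -> Haplotype:
        return tuple(
            a if s.snp_id in alt_at else r
            for s, r, a in zip(DEFAULT_SNPS, ref, alt)
        )

    all_ids = set(SNP_IDS)
    return {
        "*A1": ref,
        "*A2": mix({"rs4715333-631"}),
        "*B1a": mix(all_ids - {"rs11964968-513"}),
        "*B1b": alt,
    }


DEFAULT_STAR_TABLE: StarTable = _build_default_table()


def _validate_haplotype(
    haplotype: Sequence[str], snps: Sequence[SnpDef] = DEFAULT_SNPS
) -> Haplotype:
    if len(haplotype) != len(snps):
        raise ValueError(
            f"haplotype has {len(haplotype)} alleles, expected {len(snps)}"
        )
    for allele, snp in zip(haplotype, snps):
        if allele not in (snp.ref_allele, snp.alt_allele):
            raise ValueError(
                f"{snp.snp_id}: allele {allele!r} is neither ref "
                f"({snp.ref_allele}) nor alt ({snp.alt_allele})"
            )
    return tuple(haplotype)


def assign_star(
    haplotype: Sequence[str],
    table: Mapping[str, Haplotype] = DEFAULT_STAR_TABLE,
    snps: Sequence[SnpDef] = DEFAULT_SNPS,
) -> str:
    """Exact-match star-allele lookup for one haplotype (no fuzzy match)."""
    hap = _validate_haplotype(haplotype, snps)
    for name, alleles in table.items():
        if alleles == hap:
            return name
    return "unassigned"


def _star_sort_key(name: str) -> tuple[str, str]:
    family = name[1] if len(name) > 1 and name.startswith("*") else "~"
    return (family, name)


def name_diplotype(
    h1: Sequence[str],
    h2: Sequence[str],
    table: Mapping[str, Haplotype] = DEFAULT_STAR_TABLE,
    snps: Sequence[SnpDef] = DEFAULT_SNPS,
) -> str:
    """Name a haplotype pair: A-family before B-family, then
    lexicographic ("*A1*B1a"); two identical haplotypes are written with
    a slash ("*A1/*A1"); unassigned haplotypes propagate as
    "<star>*unassigned"."""
    s1 = assign_star(h1, table, snps)
    s2 = assign_star(h2, table, snps)
    s1 = s1 if s1 == "unassigned" else s1
    names = sorted(
        (s1 if s1 != "unassigned" else "*unassigned",
         s2 if s2 != "unassigned" else "*unassigned"),
        key=_star_sort_key,
    )
    if names[0] == names[1]:
        return f"{names[0]}/{names[1]}"
    return "".join(names)


# ---------------------------------------------------------------------------
# TSV I/O


def write_star_table(table: StarTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("star_name\t" + "\t".join(SNP_IDS) + "\n")
        for name, alleles in table.items():
            fh.write(name + "\t" + "\t".join(alleles) + "\n")


def read_star_table(path: str | Path) -> StarTable:
    table: StarTable = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "star_name" or tuple(header[1:]) != SNP_IDS:
            raise ValueError(f"{path}: bad star table header {header}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            table[parts[0]] = _validate_haplotype(tuple(parts[1:]))
    if len(set(table.values())) != len(table):
        raise ValueError(f"{path}: duplicate haplotype strings in table")
    return table
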