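"""Per-read allele extraction, the 1/3 allele-frequency filter, genotype
calls and read-mapping summary statistics.

Variant calling here is deliberately simple — the amplicon has six known
biallelic SNPs and per-site depth in the hundreds, so genotypes follow
directly from base counts after discarding reads whose base at a site has
frequency below 1/3 of the reads covering that site.  The same filter
defines which reads are *informative* for downstream pair phasing.  With
a strict below-1/3 discard, at most two alleles can be retained except
for an exact three-way third split, which is retained-as-ambiguous and
flagged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord, revcomp
from .amplicon import AmpliconReference, SnpDef
from .simulate import SimRead

MISSING = "."


def extract_alleles(
    records: Sequence[AlignmentRecord],
    reads: Sequence[SimRead],
    reference: AmpliconReference,
) -> pd.DataFrame:
    """Per-read base calls at the catalogued SNP offsets.

    Returns a DataFrame indexed by read_id with one column per snp_id;
    cells hold the observed base or NaN when the read does not cover the
    site or carries a deletion across it.  Insertions never shift the
    site assignment (they consume query only).
    """
    by_id = {r.read_id: r for r in reads}
    offsets = [s.amplicon_offset for s in reference.snps]
    snp_ids = list(reference.snp_ids)
    rows: dict[str, list] = {}
    for rec in records:
        if not rec.mapped:
            continue
        read = by_id.get(rec.read_id)
        if read is None:
            raise KeyError(f"no read sequence for {rec.read_id}")
        qseq = read.sequence if rec.strand == "+" else revcomp(read.sequence)
        consumed = sum(n for op, n in rec.cigar if op in "MIS")
        if consumed != len(qseq):
            raise ValueError(
                f"{rec.read_id}: CIGAR consumes {consumed} query bases "
                f"but read has {len(qseq)}"
            )
        calls = [np.nan] * len(offsets)
        rpos = rec.ref_offset
        qpos = 0
        for op, ln in rec.cigar:
            if op == "M":
                for k, off in enumerate(offsets):
                    if rpos <= off < rpos + ln:
                        calls[k] = qseq[qpos + (off - rpos)]
                rpos += ln
                qpos += ln
            elif op == "D":
                rpos += ln  # site deleted in the read -> missing
            elif op in "IS":
                qpos += ln
        rows[rec.read_id] = calls
    return pd.DataFrame.from_dict(rows, orient="index", columns=snp_ids)


def allele_filter(
    counts: dict[str, int], coverage: int
) -> tuple[list[str], int, bool]:
    """Apply the 1/3 frequency filter to per-base counts at one site.

    A base is retained iff count/coverage >= 1/3 (strictly-below 1/3 is
    discarded); reads carrying a non-retained base are excluded from the
    site.  Returns (retained bases, discarded read count, ambiguous flag)
    where the flag marks the exact-thirds three-way tie.  Retained bases
    are ordered by count (desc), then alphabetically.
    """
    if coverage <= 0:
        raise ValueError("coverage must be >= 1")
    retained = [
        b for b, c in counts.items() if c > 0 and 3 * c >= coverage
    ]
    retained.sort(key=lambda b: (-counts[b], b))
    discarded = coverage - sum(counts[b] for b in retained)
    return retained, discarded, len(retained) > 2


@dataclass(frozen=True)
class GenotypeCall:
    snp_id: str
    coverage: int
    counts: dict[str, int]
    retained_alleles: tuple[str, ...]
    zygosity: str  # "hom" | "het" | "nocall"
    discarded_reads: int
    flags: tuple[str, ...] = ()

    @property
    def called(self) -> bool:
        return self.zygosity != "nocall"

    @property
    def genotype(self) -> tuple[str, ...]:
        """Unphased genotype as a sorted allele pair."""
        if not self.called:
            return ()
        if self.zygosity == "hom":
            return (self.retained_alleles[0],) * 2
        return tuple(sorted(self.retained_alleles[:2]))


def call_genotype(
    table: pd.DataFrame, snp: SnpDef, min_coverage: int = 20
) -> GenotypeCall:
    """Count-and-threshold genotype call at one catalogued SNP."""
    column = table[snp.snp_id].dropna()
    counts = dict(Counter(column))
    coverage = int(column.size)
    if coverage < min_coverage:
        return GenotypeCall(
            snp.snp_id, coverage, counts, (), "nocall", 0,
            (f"coverage {coverage} < {min_coverage}",),
        )
    retained, discarded, ambiguous = allele_filter(counts, coverage)
    flags = []
    if ambiguous:
        flags.append("ambiguous_thirds")
        zygosity = "het"
    else:
        zygosity = "het" if len(retained) == 2 else "hom"
    if 3 * discarded >= coverage:  # most reads filtered away at this site
        flags.append("low_confidence")
    return GenotypeCall(
        snp.snp_id, coverage, counts, tuple(retained), zygosity,
        discarded, tuple(flags),
    )


def call_genotypes(
    table: pd.DataFrame,
    reference: AmpliconReference,
    min_coverage: int = 20,
) -> list[GenotypeCall]:
    return [call_genotype(table, s, min_coverage) for s in reference.snps]


# ---------------------------------------------------------------------------
# Read statistics


@dataclass(frozen=True)
class ReadStats:
    """Per-sample read-mapping summary (mean length to 1 decimal, % of
    amplicon to 1 decimal, % mapped to 2 decimals)."""

    sample: str
    n_reads: int
    mean_length: float
    min_length: int
    max_length: int
    pct_of_amplicon: float
    n_mapped: int
    pct_mapped: float
    flags: tuple[str, ...] = ()


def read_stats(
    reads: Sequence[SimRead],
    records: Sequence[AlignmentRecord],
    amplicon_length: int,
    sample: str = "sample",
) -> ReadStats:
    if not reads:
        return ReadStats(sample, 0, 0.0, 0, 0, 0.0, 0, 0.0, ("no_reads",))
    lengths = np.array([len(r.sequence) for r in reads])
    mean_len = float(lengths.mean())
    n_mapped = sum(1 for r in records if r.mapped)
    return ReadStats(
        sample,
        len(reads),
        round(mean_len, 1),
        int(lengths.min()),
        int(lengths.max()),
        round(mean_len / amplicon_length * 100.0, 1),
        n_mapped,
        round(n_mapped / len(reads) * 100.0, 2),
    )


_STATS_COLUMNS = (
    "sample",
    "n_reads",
    "mean_length",
    "min_length",
    "max_length",
    "pct_of_amplicon",
    "n_mapped",
    "pct_mapped",
)


def stats_to_frame(stats: Sequence[ReadStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(s, c) for c in _STATS_COLUMNS] for s in stats],
        columns=_STATS_COLUMNS,
    )


def write_stats(stats: Sequence[ReadStats], path: str | Path) -> None:
    stats_to_frame(stats).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF output


def write_vcf(
    calls: Sequence[GenotypeCall],
    reference: AmpliconReference,
    path: str | Path,
) -> None:
    """Write genotype calls as VCFv4.2 in amplicon coordinates
    (POS = amplicon_offset + 1; INFO DP and AD; FILTER lowcov)."""
    by_id = {c.snp_id: c for c in calls}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference.name},length={len(reference)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##INFO=<ID=AD,Number=R,Type=Integer,'
            'Description="Read depth per allele (ref, alt)">\n'
        )
        fh.write('##FILTER=<ID=lowcov,Description="Coverage below threshold">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snp in reference.snps:
            call = by_id.get(snp.snp_id)
            if call is None:
                continue
            dp = call.coverage
            ad_ref = call.counts.get(snp.ref_allele, 0)
            ad_alt = call.counts.get(snp.alt_allele, 0)
            alt = snp.alt_allele if ad_alt > 0 else "."
            filt = "PASS" if call.called else "lowcov"
            fh.write(
                f"{reference.name}\t{snp.amplicon_offset + 1}\t{snp.snp_id}"
                f"\t{snp.ref_allele}\t{alt}\t.\t{filt}"
                f"\tDP={dp};AD={ad_ref},{ad_alt}\n"
            )
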