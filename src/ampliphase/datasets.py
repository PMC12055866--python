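"""Reference datasets: the eight 1000 Genomes LCL cell lines whose GSTA1
promoter diplotypes were characterized by nanopore amplicon sequencing,
with their published per-sample read-mapping summaries.

The published study deposited no raw reads, so these printed tables are
the only real-data anchor: the diplotypes drive clean-simulation
round-trip checks and the read summaries exercise the Table-style
aggregation arithmetic.
"""

from __future__ import annotations

import pandas as pd

from .amplicon import SNP_IDS

#: Diplotypes of the eight cell lines as (star_1, star_2) haplotype names.
CELL_LINE_DIPLOTYPES: dict[str, tuple[str, str]] = {
    "NA06985": ("*A1", "*B1a"),
    "NA07056": ("*A1", "*B1a"),
    "NA07357": ("*A1", "*B1b"),
    "NA11840": ("*A1", "*B1a"),
    "NA12043": ("*A2", "*B1a"),
    "NA12762": ("*A1", "*B1a"),
    "NA12872": ("*A1", "*B1a"),
    "NA12874": ("*A1", "*B1a"),
}

#: Published per-sample read-mapping summaries:
#: (n_reads, mean_length, min_length, max_length, pct_of_amplicon,
#:  n_mapped, pct_mapped)
READ_SUMMARIES: dict[str, tuple[int, float, int, int, float, int, float]] = {
    "NA06985": (1039, 822.6, 37, 9184, 61.5, 1031, 99.23),
    "NA07056": (505, 789.4, 136, 9235, 59.1, 502, 99.41),
    "NA07357": (664, 813.0, 34, 5462, 60.9, 656, 98.80),
    "NA11840": (693, 821.4, 43, 6625, 61.5, 648, 93.51),
    "NA12043": (881, 816.9, 127, 5266, 61.1, 862, 97.84),
    "NA12762": (1108, 812.3, 40, 9171, 60.9, 1090, 98.38),
    "NA12872": (776, 799.2, 83, 4626, 59.8, 766, 98.71),
    "NA12874": (892, 835.5, 43, 9417, 62.5, 880, 98.65),
}

_SUMMARY_COLUMNS = (
    "n_reads",
    "mean_length",
    "min_length",
    "max_length",
    "pct_of_amplicon",
    "n_mapped",
    "pct_mapped",
)


def read_summary_frame() -> pd.DataFrame:
    """Published per-sample summaries as a DataFrame (index: cell line)."""
    return pd.DataFrame.from_dict(
        READ_SUMMARIES, orient="index", columns=_SUMMARY_COLUMNS
    )


def aggregate_read_summaries(
    frame: pd.DataFrame | None = None, amplicon_length: int = 1336
) -> dict[str, float]:
    """Across-sample means in the published precision, plus the overall
    mapped fraction recomputed from counts.

    Mean read count and mean mapped count are rounded to integers, mean
    length to 1 decimal; the percent-of-amplicon mean is recomputed from
    the unrounded mean length (per-sample printed percentages do not all
    recompute exactly from their printed rounded means).
    """
    df = read_summary_frame() if frame is None else frame
    mean_len = float(df["mean_length"].mean())
    return {
        "mean_n_reads": round(float(df["n_reads"].mean())),
        "mean_read_length": round(mean_len, 1),
        "mean_pct_of_amplicon": round(mean_len / amplicon_length * 100.0, 1),
        "mean_n_mapped": round(float(df["n_mapped"].mean())),
        "mean_pct_mapped": round(float(df["pct_mapped"].mean()), 2),
        "overall_pct_mapped": round(
            float(df["n_mapped"].sum()) / float(df["n_reads"].sum()) * 100.0, 2
        ),
    }


def diplotype_alleles(
    cell_line: str, star_table: dict[str, tuple[str, ...]]
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """The two haplotype allele tuples (catalog order) of a cell line."""
    s1, s2 = CELL_LINE_DIPLOTYPES[cell_line]
    return star_table[s1], star_table[s2]


def genotype_columns(
    cell_line: str, star_table: dict[str, tuple[str, ...]]
) -> dict[str, tuple[str, str]]:
    """Expected unphased genotype (sorted allele pair) per snp_id."""
    h1, h2 = diplotype_alleles(cell_line, star_table)
    return {
        snp_id: tuple(sorted((a, b)))
        for snp_id, a, b in zip(SNP_IDS, h1, h2)
    }
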