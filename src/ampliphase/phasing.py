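"""Read-backed phasing: the pairwise proportion-of-correct-haplotypes
statistic, its distance decay, exhaustive diplotype phasing and a
per-bp hybrid-rate estimator.

The central quantity is, for every pair of heterozygous SNPs, the
proportion of informative reads (reads carrying a retained allele at
both sites) whose allele pair belongs to the majority perfect matching
between the two sites' alleles.  True molecules all support one of the
two perfect matchings, so the statistic is 1 in clean data, is pulled
toward 0.5 by PCR hybrids with a breakpoint between the sites (hence the
decay with inter-SNP distance), and sits on a floor set by sequencing
errors for nearby pairs.

Diplotype phasing is exhaustive: with k heterozygous sites there are
2^(k-1) phase configurations, each scored by summing over reads the
better of the agreements with the two haplotypes; the argmax is the
called diplotype.  This is exact — no heuristic search — and practical
for amplicon-scale k.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .align import Scoring, align_reads
from .amplicon import AmpliconReference, pairwise_distance
from .genotype import GenotypeCall, call_genotypes, extract_alleles
from .simulate import MoleculePool, PcrConfig, ReadModel, simulate_pcr, simulate_reads


@dataclass(frozen=True)
class PairPhasingResult:
    """2x2 read counts and the majority-pairing proportion for one pair
    of heterozygous SNPs."""

    snp_a: str
    snp_b: str
    distance: int
    alleles_a: tuple[str, str]
    alleles_b: tuple[str, str]
    counts: np.ndarray  # 2x2, rows alleles_a, cols alleles_b
    n_informative: int
    correct_pairing: tuple[tuple[str, str], tuple[str, str]]
    prop_correct: float
    ambiguous: bool
    valid: bool = True
    reason: str | None = None

    @staticmethod
    def invalid(snp_a: str, snp_b: str, distance: int, reason: str) -> "PairPhasingResult":
        return PairPhasingResult(
            snp_a, snp_b, distance, ("", ""), ("", ""),
            np.zeros((2, 2), dtype=int), 0, (("", ""), ("", "")),
            float("nan"), False, valid=False, reason=reason,
        )


def pairwise_concordance(
    table: pd.DataFrame,
    call_a: GenotypeCall,
    call_b: GenotypeCall,
    distance: int,
) -> PairPhasingResult:
    """Proportion of reads carrying the majority haplotype pairing for
    one heterozygous SNP pair.

    Reads are restricted to those with a retained allele at both sites;
    the "correct" pairing is whichever perfect matching of the two
    allele pairs — {(a1,b1),(a2,b2)} or {(a1,b2),(a2,b1)} — has the
    larger read count.  A tie is flagged ambiguous and the
    lexicographically smallest pairing is reported.
    """
    sa, sb = call_a.snp_id, call_b.snp_id
    for call in (call_a, call_b):
        if call.zygosity != "het":
            return PairPhasingResult.invalid(
                sa, sb, distance, f"{call.snp_id} is not heterozygous"
            )
    a1, a2 = call_a.retained_alleles[:2]
    b1, b2 = call_b.retained_alleles[:2]
    col_a = table[sa].to_numpy()
    col_b = table[sb].to_numpy()
    counts = np.zeros((2, 2), dtype=int)
    for i, aa in enumerate((a1, a2)):
        mask_a = col_a == aa
        for j, bb in enumerate((b1, b2)):
            counts[i, j] = int(np.sum(mask_a & (col_b == bb)))
    n_inf = int(counts.sum())
    if n_inf == 0:
        return PairPhasingResult.invalid(sa, sb, distance, "no informative reads")
    cis = int(counts[0, 0] + counts[1, 1])
    trans = int(counts[0, 1] + counts[1, 0])
    pairing_cis = ((a1, b1), (a2, b2))
    pairing_trans = ((a1, b2), (a2, b1))
    if cis > trans:
        pairing, ambiguous = pairing_cis, False
    elif trans > cis:
        pairing, ambiguous = pairing_trans, False
    else:
        pairing = min(
            tuple(sorted(pairing_cis)), tuple(sorted(pairing_trans))
        )
        ambiguous = True
    return PairPhasingResult(
        sa, sb, distance, (a1, a2), (b1, b2), counts, n_inf,
        tuple(sorted(pairing)), max(cis, trans) / n_inf, ambiguous,
    )


def all_pair_concordances(
    table: pd.DataFrame,
    calls: Sequence[GenotypeCall],
    reference: AmpliconReference,
    het_only: bool = True,
) -> list[PairPhasingResult]:
    """Concordance for every (het) SNP pair, sorted by distance."""
    by_id = {c.snp_id: c for c in calls}
    results = []
    for snp_a, snp_b in itertools.combinations(reference.snps, 2):
        ca, cb = by_id.get(snp_a.snp_id), by_id.get(snp_b.snp_id)
        if ca is None or cb is None:
            continue
        if het_only and not (ca.zygosity == "het" and cb.zygosity == "het"):
            continue
        results.append(
            pairwise_concordance(table, ca, cb, pairwise_distance(snp_a, snp_b))
        )
    return sorted(results, key=lambda r: r.distance)


# ---------------------------------------------------------------------------
# Distance decay


def distance_decay(
    results: Sequence[PairPhasingResult],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Decay table (pair, distance, prop_correct) sorted by distance,
    plus summaries: the minimum proportion among pairs closer than
    200 bp and the proportion at the maximum distance."""
    valid = [r for r in results if r.valid]
    if not valid:
        raise ValueError("no valid pair results")
    df = pd.DataFrame(
        {
            "snp_a": [r.snp_a for r in valid],
            "snp_b": [r.snp_b for r in valid],
            "distance": [r.distance for r in valid],
            "n_informative": [r.n_informative for r in valid],
            "prop_correct": [r.prop_correct for r in valid],
            "ambiguous": [r.ambiguous for r in valid],
        }
    ).sort_values(["distance", "snp_a"], kind="mergesort", ignore_index=True)
    short = df[df["distance"] < 200]
    summary = {
        "min_prop_below_200bp": float(short["prop_correct"].min())
        if len(short)
        else float("nan"),
        "max_distance": float(df["distance"].max()),
        "prop_at_max_distance": float(
            df.loc[df["distance"].idxmax(), "prop_correct"]
        ),
    }
    return df, summary


@dataclass(frozen=True)
class ChimeraEstimate:
    """Hybrid load summarised as an error floor (short-range discordance)
    plus a per-bp excess-discordance slope."""

    error_floor: float
    per_bp_rate: float
    excess: pd.DataFrame  # pair, distance, excess discordance


def estimate_hybrid_rate(
    results: Sequence[PairPhasingResult], short_range: int = 200
) -> ChimeraEstimate:
    """Estimate the per-bp hybrid-haplotype rate from a decay table.

    The discordance 1 - prop_correct of pairs closer than ``short_range``
    (weighted by informative reads) estimates the sequencing-error floor;
    the least-squares through-origin slope of the above-floor excess
    against distance estimates the per-bp hybrid rate.
    """
    valid = [r for r in results if r.valid]
    short = [r for r in valid if r.distance < short_range]
    if not short:
        raise ValueError(f"no pair closer than {short_range} bp")
    weights = np.array([r.n_informative for r in short], dtype=float)
    disc_short = np.array([1.0 - r.prop_correct for r in short])
    floor = float(np.average(disc_short, weights=weights))
    dist = np.array([r.distance for r in valid], dtype=float)
    excess = np.maximum(
        0.0, np.array([1.0 - r.prop_correct for r in valid]) - floor
    )
    slope = float((dist * excess).sum() / (dist * dist).sum())
    frame = pd.DataFrame(
        {
            "snp_a": [r.snp_a for r in valid],
            "snp_b": [r.snp_b for r in valid],
            "distance": dist.astype(int),
            "excess_discordance": excess,
        }
    )
    return ChimeraEstimate(floor, max(0.0, slope), frame)


# ---------------------------------------------------------------------------
# Exhaustive diplotype phasing


@dataclass(frozen=True)
class DiplotypeCall:
    """Best-scoring haplotype pair over the catalogued SNPs."""

    haplotype_1: tuple[str, ...]
    haplotype_2: tuple[str, ...]
    n_het_sites: int
    score: int
    n_reads_consistent: int
    ties: bool
    flags: tuple[str, ...] = ()


MAX_HET_SITES = 12


def phase_diplotype(
    table: pd.DataFrame,
    calls: Sequence[GenotypeCall],
    reference: AmpliconReference,
) -> DiplotypeCall:
    """Exhaustively phase the diplotype from the read-allele table.

    Homozygous sites are filled directly; the 2^(k-1) phase
    configurations over the k heterozygous sites are each scored as the
    sum over reads of the better agreement with the two haplotypes
    (agreement counted over the read's covered het sites with retained
    alleles).  Ties are flagged and broken lexicographically on
    haplotype 1.
    """
    by_id = {c.snp_id: c for c in calls}
    het_ids = [
        s.snp_id
        for s in reference.snps
        if by_id.get(s.snp_id) and by_id[s.snp_id].zygosity == "het"
    ]
    k = len(het_ids)
    if k > MAX_HET_SITES:
        raise ValueError(
            f"{k} heterozygous sites exceed the exhaustive bound "
            f"{MAX_HET_SITES}"
        )
    flags: list[str] = []
    # fixed (hom / nocall) alleles
    fixed: dict[str, str] = {}
    for s in reference.snps:
        call = by_id.get(s.snp_id)
        if call is None or not call.called:
            fixed[s.snp_id] = "N"
            flags.append(f"{s.snp_id}:nocall")
        elif call.zygosity == "hom":
            fixed[s.snp_id] = call.retained_alleles[0]

    if k == 0:
        hap = tuple(fixed[s.snp_id] for s in reference.snps)
        n_cons = int(len(table))
        return DiplotypeCall(hap, hap, 0, n_cons, n_cons, False, tuple(flags))

    # per-het-site allele pair, alphabetical so +1 codes the smaller allele
    pairs = {
        sid: tuple(sorted(by_id[sid].retained_alleles[:2])) for sid in het_ids
    }
    sub = table[het_ids].to_numpy()
    n_reads = sub.shape[0]
    R = np.zeros((n_reads, k), dtype=np.int8)
    for j, sid in enumerate(het_ids):
        R[sub[:, j] == pairs[sid][0], j] = 1
        R[sub[:, j] == pairs[sid][1], j] = -1
    covered = (R != 0).sum(axis=1)

    # all configurations with v[0] = +1
    configs = np.array(
        [
            (1,) + tail
            for tail in itertools.product((1, -1), repeat=k - 1)
        ],
        dtype=np.int8,
    ).T  # k x C
    agree = np.abs(R.astype(np.int32) @ configs.astype(np.int32))  # n x C
    totals = (agree.sum(axis=0) + covered.sum()) // 2

    best = int(totals.max())
    winners = np.flatnonzero(totals == best)

    def hap_strings(v: np.ndarray) -> tuple[tuple[str, ...], tuple[str, ...]]:
        h1, h2 = [], []
        vi = dict(zip(het_ids, v))
        for s in reference.snps:
            if s.snp_id in vi:
                a, b = pairs[s.snp_id]
                h1.append(a if vi[s.snp_id] == 1 else b)
                h2.append(b if vi[s.snp_id] == 1 else a)
            else:
                h1.append(fixed[s.snp_id])
                h2.append(fixed[s.snp_id])
        return tuple(h1), tuple(h2)

    options = sorted(
        ((hap_strings(configs[:, w]), w) for w in winners),
        key=lambda item: item[0][0],
    )
    (h1, h2), w_best = options[0]
    ties = len({hp[0] for hp, _ in options}) > 1
    if ties:
        flags.append("phase_tie")
    # count reads fully consistent with one of the two haplotypes
    v_best = configs[:, w_best]
    dot = R.astype(np.int32) @ v_best.astype(np.int32)
    n_cons = int(np.sum((np.abs(dot) == covered) & (covered > 0)))
    return DiplotypeCall(h1, h2, k, best, n_cons, ties, tuple(flags))


# ---------------------------------------------------------------------------
# Cycle / input-DNA sweep


@dataclass(frozen=True)
class SweepCondition:
    cycles: int
    input_ng: float
    pool_size: int
    sufficient: bool
    chimeric_fraction: float
    decay: pd.DataFrame | None = None
    summary: dict[str, float] | None = None
    estimate: ChimeraEstimate | None = None


#: Minimum post-PCR yield (molecules) for a sequencable condition
#: (~1/3 of pool capacity; conditions stopping short of the plateau fail).
DEFAULT_MIN_YIELD = 35_000


def run_cycle_sweep(
    haplotypes: tuple[Sequence[str], Sequence[str]],
    reference: AmpliconReference,
    cycles_grid: Sequence[int] = (15, 20, 25, 30, 35, 40),
    input_ng_grid: Sequence[float] = (20.0, 120.0),
    base_config: PcrConfig | None = None,
    read_model: ReadModel | None = None,
    n_reads: int = 2000,
    min_yield: int = DEFAULT_MIN_YIELD,
    min_coverage: int = 20,
    seed: int = 0,
    full_pipeline: bool = True,
) -> list[SweepCondition]:
    """Run the PCR-condition sweep: one simulation per (cycles, input)
    pair; conditions whose final pool is below ``min_yield`` molecules
    are reported insufficient (not sequenced), mirroring low-cycle PCRs
    that do not produce enough DNA."""
    base = base_config or PcrConfig()
    conditions = []
    for ci, cycles in enumerate(cycles_grid):
        for gi, ng in enumerate(input_ng_grid):
            run_seed = (seed * 1_000_003 + ci * 101 + gi) % (2**31)
            cfg = PcrConfig(
                n0_per_haplotype=PcrConfig.n0_for_ng(ng),
                cycles=cycles,
                efficiency0=base.efficiency0,
                chimera_rate0=base.chimera_rate0,
                capacity=base.capacity,
                seed=run_seed,
            )
            pool = simulate_pcr(haplotypes, cfg, length=len(reference))
            sufficient = len(pool) >= min_yield
            decay = summary = estimate = None
            if sufficient and full_pipeline:
                reads, _ = simulate_reads(
                    pool, reference, n_reads, read_model, seed=run_seed + 1
                )
                records = align_reads(reads, reference)
                tbl = extract_alleles(records, reads, reference)
                calls = call_genotypes(tbl, reference, min_coverage)
                results = all_pair_concordances(tbl, calls, reference)
                if any(r.valid for r in results):
                    decay, summary = distance_decay(results)
                    try:
                        estimate = estimate_hybrid_rate(results)
                    except ValueError:
                        estimate = None
            conditions.append(
                SweepCondition(
                    cycles, ng, len(pool), sufficient,
                    pool.chimeric_fraction, decay, summary, estimate,
                )
            )
    return conditions
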