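"""Truth-annotated synthetic data: PCR amplification with cycle-dependent
hybrid (chimeric) haplotype formation, and nanopore-like reads.

PCR model
---------
The pool starts from ``n0_per_haplotype`` template molecules per haplotype
of a diploid sample.  Each cycle, every molecule duplicates with
probability ``e_c = efficiency0 * max(0, 1 - pool/K)`` — a logistic
plateau: amplification stalls as the pool approaches the reagent capacity
``K``.  Each new strand is the product of a template-switch (chimera)
event with probability ``chi_c = chimera_rate0 * min(1, pool/K)``:
incompletely extended strands accumulate as primers are exhausted and
re-prime on another molecule, so switching is rare in the exponential
phase and approaches ``chimera_rate0`` at the plateau.  A switch draws a
breakpoint uniformly on [1, L-1] and copies the suffix from a uniformly
drawn *other* pool molecule; mosaics compose, so late-cycle molecules can
carry several breakpoints.  Extension/annealing time are deliberately not
model parameters: the study found they do not influence hybrid formation.

A molecule is *chimeric* when its (merged) mosaic contains segments from
both haplotypes.  A switch between molecules that agree over the whole
suffix yields a non-chimeric product and is counted as such.

The pool is represented compactly — pure molecules as per-haplotype
counts, chimeric molecules individually — which is exact because pure
molecules of one haplotype are exchangeable.  Tests compare this against
a naive molecule-by-molecule simulation.

Read model
----------
Each read samples a pool molecule uniformly, truncates each end
independently (probability ``trunc_prob``, amount uniform on
[0, trunc_max] bp), is rejected and redrawn entirely if shorter than
``min_len``, and then receives uniform substitution / insertion /
deletion errors.  The truncation defaults were calibrated numerically so
that 10,000 default reads of a 1336-bp amplicon have a mean length of
~813 bp and relative coverage of ~0.5 at the amplicon ends — the read
profile reported for the study this package models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .amplicon import AMPLICON_LENGTH, AmpliconReference

# Desk-scale molecule equivalents: 20 ng of genomic DNA maps to 75 input
# molecules per haplotype.  Only relative input matters for the sweeps; the
# pool is scaled so the yield plateau falls near cycle 25 (as observed)
# while remaining simulable molecule-by-molecule.
MOLECULES_PER_HAPLOTYPE_PER_20NG = 75

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0..3."""
    codes = _BASE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode()


Mosaic = tuple[tuple[int, int, int], ...]  # ((start, end, haplotype_id), ...)


def merge_mosaic(segments: Sequence[tuple[int, int, int]]) -> Mosaic:
    """Merge adjacent same-haplotype segments; drop empty ones."""
    merged: list[tuple[int, int, int]] = []
    for s, e, h in segments:
        if e <= s:
            continue
        if merged and merged[-1][2] == h and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e, h)
        else:
            merged.append((s, e, h))
    return tuple(merged)


def mosaic_is_chimeric(mosaic: Mosaic) -> bool:
    return len({h for _, _, h in mosaic}) > 1


def compose_mosaic(prefix: Mosaic, suffix: Mosaic, breakpoint: int) -> Mosaic:
    """Mosaic of a strand copied from ``prefix`` up to ``breakpoint`` and
    from ``suffix`` afterwards."""
    parts = [(s, min(e, breakpoint), h) for s, e, h in prefix if s < breakpoint]
    parts += [(max(s, breakpoint), e, h) for s, e, h in suffix if e > breakpoint]
    return merge_mosaic(parts)


def format_mosaic(mosaic: Mosaic) -> str:
    return ";".join(f"{s}-{e}:{h}" for s, e, h in mosaic)


def parse_mosaic(text: str) -> Mosaic:
    segs = []
    for part in text.split(";"):
        span, h = part.split(":")
        s, e = span.split("-")
        segs.append((int(s), int(e), int(h)))
    return tuple(segs)


@dataclass(frozen=True)
class TemplateMolecule:
    """A PCR product as an ordered mosaic of haplotype-of-origin segments."""

    molecule_id: str
    mosaic: Mosaic
    birth_cycle: int = 0

    @property
    def is_chimeric(self) -> bool:
        return mosaic_is_chimeric(self.mosaic)


@dataclass(frozen=True)
class PcrConfig:
    """Parameters of the logistic-plateau PCR/chimera model."""

    n0_per_haplotype: int = MOLECULES_PER_HAPLOTYPE_PER_20NG
    cycles: int = 40
    efficiency0: float = 0.30
    chimera_rate0: float = 0.5
    capacity: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if self.n0_per_haplotype < 0 or self.capacity < 0:
            raise ValueError("n0_per_haplotype and capacity must be >= 0")
        for name in ("efficiency0", "chimera_rate0"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @staticmethod
    def n0_for_ng(ng: float) -> int:
        """Desk-scale molecule count per haplotype for a DNA input in ng."""
        return int(round(ng / 20.0 * MOLECULES_PER_HAPLOTYPE_PER_20NG))


class MoleculePool:
    """Compact post-PCR pool: pure molecules as counts, chimerics listed.

    ``haplotypes`` are the two allele tuples (catalog order) of the diploid
    sample the pool was amplified from.
    """

    def __init__(
        self,
        haplotypes: tuple[Sequence[str], Sequence[str]],
        length: int,
        n_pure: Sequence[int],
        chimeric: list[tuple[Mosaic, int]],
    ) -> None:
        self.haplotypes = (tuple(haplotypes[0]), tuple(haplotypes[1]))
        self.length = length
        self.n_pure = np.asarray(n_pure, dtype=np.int64)
        self.chimeric = chimeric  # list of (mosaic, birth_cycle)

    def __len__(self) -> int:
        return int(self.n_pure.sum()) + len(self.chimeric)

    @property
    def chimeric_count(self) -> int:
        return len(self.chimeric)

    @property
    def chimeric_fraction(self) -> float:
        n = len(self)
        return len(self.chimeric) / n if n else 0.0

    def molecules(self) -> Iterator[TemplateMolecule]:
        L = self.length
        for h in (0, 1):
            for i in range(int(self.n_pure[h])):
                yield TemplateMolecule(f"pure{h}_{i}", ((0, L, h),), 0)
        for j, (mosaic, birth) in enumerate(self.chimeric):
            yield TemplateMolecule(f"chimera_{j}", mosaic, birth)

    # -- allele bookkeeping used by the read simulator ---------------------

    def molecule_label(self, index: int) -> str:
        n0, n1 = int(self.n_pure[0]), int(self.n_pure[1])
        if index < n0:
            return f"pure0_{index}"
        if index < n0 + n1:
            return f"pure1_{index - n0}"
        return f"chimera_{index - n0 - n1}"

    def molecule_mosaic(self, index: int) -> Mosaic:
        n0, n1 = int(self.n_pure[0]), int(self.n_pure[1])
        if index < n0:
            return ((0, self.length, 0),)
        if index < n0 + n1:
            return ((0, self.length, 1),)
        return self.chimeric[index - n0 - n1][0]

    def allele_code_matrix(self, reference: AmpliconReference) -> np.ndarray:
        """(2 + n_chimeric) x n_snps matrix of base codes: rows 0/1 are the
        pure haplotypes, following rows the chimeric molecules."""
        offsets = reference.snp_offsets
        hap_codes = np.stack(
            [encode_seq("".join(h)) for h in self.haplotypes], axis=0
        )
        rows = [hap_codes[0], hap_codes[1]]
        for mosaic, _ in self.chimeric:
            row = np.empty(len(offsets), dtype=np.uint8)
            for k, off in enumerate(offsets):
                for s, e, h in mosaic:
                    if s <= off < e:
                        row[k] = hap_codes[h, k]
                        break
            rows.append(row)
        return np.stack(rows, axis=0)

    def molecule_row_indices(self) -> np.ndarray:
        """Map molecule index -> row of :meth:`allele_code_matrix`."""
        n0, n1 = int(self.n_pure[0]), int(self.n_pure[1])
        idx = np.empty(len(self), dtype=np.int64)
        idx[:n0] = 0
        idx[n0 : n0 + n1] = 1
        idx[n0 + n1 :] = 2 + np.arange(len(self.chimeric))
        return idx


def simulate_pcr(
    haplotypes: tuple[Sequence[str], Sequence[str]],
    cfg: PcrConfig,
    length: int = AMPLICON_LENGTH,
) -> MoleculePool:
    """Amplify a diploid sample under the logistic-plateau chimera model.

    Deterministic given ``cfg.seed``.  Random draws per cycle, in order:
    duplication counts for the two pure classes, the per-chimeric-molecule
    duplication mask, switch-event counts/masks, then per switch event the
    parent position (pure classes only), breakpoint and partner.  Partners
    are drawn from the start-of-cycle pool; new strands enter the pool at
    the end of the cycle.
    """
    if len(haplotypes) != 2:
        raise ValueError("exactly two haplotypes required")
    if cfg.n0_per_haplotype == 0:
        raise ValueError("empty pool: n0_per_haplotype must be > 0")
    rng = np.random.default_rng(cfg.seed)
    L = length
    n_pure = np.array([cfg.n0_per_haplotype, cfg.n0_per_haplotype], dtype=np.int64)
    chimeric: list[tuple[Mosaic, int]] = []
    K = cfg.capacity

    for cycle in range(1, cfg.cycles + 1):
        n0, n1 = int(n_pure[0]), int(n_pure[1])
        n_chim = len(chimeric)
        pool = n0 + n1 + n_chim
        load = pool / K if K > 0 else 1.0
        e_c = cfg.efficiency0 * max(0.0, 1.0 - load)
        chi_c = cfg.chimera_rate0 * min(1.0, load)
        if e_c <= 0.0:
            continue

        dup_pure = rng.binomial([n0, n1], e_c)
        dup_chim_mask = (
            rng.random(n_chim) < e_c if n_chim else np.zeros(0, dtype=bool)
        )
        # how many duplicates arise from a template switch
        switch_pure = rng.binomial(dup_pure, chi_c)
        n_dup_chim = int(dup_chim_mask.sum())
        switch_chim_mask = (
            rng.random(n_dup_chim) < chi_c
            if n_dup_chim
            else np.zeros(0, dtype=bool)
        )

        new_pure = dup_pure - switch_pure  # faithful copies stay pure
        new_chimeric: list[tuple[Mosaic, int]] = []
        class_bounds = (n0, n0 + n1)

        def partner_mosaic(parent_index: int) -> Mosaic:
            p = int(rng.integers(0, pool - 1))
            if p >= parent_index:
                p += 1
            if p < class_bounds[0]:
                return ((0, L, 0),)
            if p < class_bounds[1]:
                return ((0, L, 1),)
            return chimeric[p - class_bounds[1]][0]

        def do_switch(parent_index: int, parent_mosaic: Mosaic) -> None:
            bp = int(rng.integers(1, L))
            mosaic = compose_mosaic(parent_mosaic, partner_mosaic(parent_index), bp)
            if mosaic_is_chimeric(mosaic):
                new_chimeric.append((mosaic, cycle))
            else:
                new_pure[mosaic[0][2]] += 1

        for h in (0, 1):
            base = 0 if h == 0 else n0
            class_n = n0 if h == 0 else n1
            for _ in range(int(switch_pure[h])):
                parent = base + int(rng.integers(0, class_n))
                do_switch(parent, ((0, L, h),))
        chim_dup_indices = np.nonzero(dup_chim_mask)[0]
        for j, idx in enumerate(chim_dup_indices):
            mosaic = chimeric[idx][0]
            if switch_chim_mask[j]:
                do_switch(class_bounds[1] + int(idx), mosaic)
            else:
                new_chimeric.append((mosaic, cycle))

        n_pure += new_pure
        chimeric.extend(new_chimeric)

    return MoleculePool(haplotypes, L, n_pure, chimeric)


# ---------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class ReadModel:
    """Nanopore-like read length/error model.

    Truncation defaults (prob 0.654/side, max 897 bp, min length 50) were
    solved by exact enumeration so that default reads of a 1336-bp
    amplicon average ~813 bp with ~50% relative coverage at the ends.
    """

    error_sub: float = 0.05
    error_ins: float = 0.01
    error_del: float = 0.01
    trunc_prob: float = 0.654
    trunc_max: int = 897
    min_len: int = 50

    def __post_init__(self) -> None:
        for name in ("error_sub", "error_ins", "error_del", "trunc_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.trunc_max < 0 or self.min_len < 0:
            raise ValueError("trunc_max and min_len must be >= 0")

    @property
    def phred_quality(self) -> int:
        total = self.error_sub + self.error_ins + self.error_del
        if total <= 0:
            return 40
        return max(2, min(40, int(round(-10.0 * math.log10(total)))))


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class ReadTruth:
    """Ground-truth sidecar for one simulated read."""

    read_id: str
    molecule_id: str
    mosaic: Mosaic
    trunc_left: int
    trunc_right: int
    n_sub: int
    n_ins: int
    n_del: int

    @property
    def is_chimeric(self) -> bool:
        return mosaic_is_chimeric(self.mosaic)


def simulate_reads(
    pool: MoleculePool,
    reference: AmpliconReference,
    n_reads: int,
    model: ReadModel | None = None,
    seed: int = 0,
) -> tuple[list[SimRead], list[ReadTruth]]:
    """Sample reads from a pool under the truncation/error model.

    Each read picks a molecule uniformly; each end is truncated
    independently with probability ``trunc_prob`` by Uniform{0..trunc_max}
    bp; reads shorter than ``min_len`` are rejected and redrawn entirely.
    Substitutions are uniform over the three alternative bases.
    Deterministic given ``seed``; reads are emitted on the plus strand.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if len(pool) == 0:
        raise ValueError("empty molecule pool")
    model = model or ReadModel()
    rng = np.random.default_rng(seed)
    L = pool.length
    ref_codes = encode_seq(reference.sequence)
    offsets = reference.snp_offsets
    allele_rows = pool.allele_code_matrix(reference)
    row_of_molecule = pool.molecule_row_indices()
    q_char = chr(model.phred_quality + 33)

    reads: list[SimRead] = []
    truths: list[ReadTruth] = []
    while len(reads) < n_reads:
        batch = max(64, int((n_reads - len(reads)) * 1.3))
        mol = rng.integers(0, len(pool), batch)
        t_left = np.where(
            rng.random(batch) < model.trunc_prob,
            rng.integers(0, model.trunc_max + 1, batch),
            0,
        )
        t_right = np.where(
            rng.random(batch) < model.trunc_prob,
            rng.integers(0, model.trunc_max + 1, batch),
            0,
        )
        keep = (L - t_left - t_right) >= model.min_len
        for m, tl, tr in zip(mol[keep], t_left[keep], t_right[keep]):
            if len(reads) >= n_reads:
                break
            start, end = int(tl), L - int(tr)
            seq = ref_codes[start:end].copy()
            in_span = (offsets >= start) & (offsets < end)
            seq[offsets[in_span] - start] = allele_rows[
                row_of_molecule[m], in_span
            ]
            n = seq.size
            sub_mask = rng.random(n) < model.error_sub
            n_sub = int(sub_mask.sum())
            if n_sub:
                shift = rng.integers(1, 4, n_sub).astype(np.uint8)
                seq[sub_mask] = (seq[sub_mask] + shift) % 4
            del_mask = rng.random(n) < model.error_del
            n_del = int(del_mask.sum())
            ins_mask = rng.random(n + 1) < model.error_ins
            n_ins = int(ins_mask.sum())
            if n_del or n_ins:
                pieces: list[np.ndarray] = []
                ins_bases = rng.integers(0, 4, n_ins).astype(np.uint8)
                ins_pos = np.nonzero(ins_mask)[0]
                kept = ~del_mask
                prev = 0
                for b, pos in zip(ins_bases, ins_pos):
                    pieces.append(seq[prev:pos][kept[prev:pos]])
                    pieces.append(np.array([b], dtype=np.uint8))
                    prev = pos
                pieces.append(seq[prev:][kept[prev:]])
                seq = np.concatenate(pieces)
            rid = f"read{len(reads):06d}"
            reads.append(SimRead(rid, decode_seq(seq), q_char * seq.size))
            truths.append(
                ReadTruth(
                    rid,
                    pool.molecule_label(int(m)),
                    pool.molecule_mosaic(int(m)),
                    int(tl),
                    int(tr),
                    n_sub,
                    n_ins,
                    n_del,
                )
            )
    return reads, truths


# ---------------------------------------------------------------------------
# File I/O


def write_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[SimRead]:
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append(SimRead(rec.id, str(rec.seq).upper(), qual))
    return reads


_TRUTH_COLUMNS = (
    "read_id",
    "molecule_id",
    "mosaic",
    "trunc_left",
    "trunc_right",
    "n_sub",
    "n_ins",
    "n_del",
)


def write_truth(truths: Sequence[ReadTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.molecule_id}\t{format_mosaic(t.mosaic)}"
                f"\t{t.trunc_left}\t{t.trunc_right}"
                f"\t{t.n_sub}\t{t.n_ins}\t{t.n_del}\n"
            )


def read_truth(path: str | Path) -> list[ReadTruth]:
    truths = []
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != _TRUTH_COLUMNS:
            raise ValueError(f"{path}: bad truth header {header}")
        for line in fh:
            if not line.strip():
                continue
            rid, mid, mosaic, tl, tr, ns, ni, nd = line.rstrip("\n").split("\t")
            truths.append(
                ReadTruth(
                    rid, mid, parse_mosaic(mosaic),
                    int(tl), int(tr), int(ns), int(ni), int(nd),
                )
            )
    return truths
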