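"""Semiglobal read-to-amplicon alignment and coverage profiles.

Reads are aligned to the single amplicon reference with a banded
affine-gap semiglobal aligner (end gaps on the reference are free, the
whole read must align).  This replaces a general-purpose mapper at desk
scale: there is one 1336-bp target, reads are near-complete subsequences
of it, and a band of a few tens of bp around the seeded diagonal is ample
at nanopore error rates.  SAM import/export keeps the pipeline
interoperable with any external aligner.

Scoring: match +2, mismatch -4; a gap of length g costs
``gap_open + g * gap_extend`` (defaults -4 and -2, so a 1-bp gap scores
-6).  A read is reported unmapped when its aligned identity (matches over
alignment columns) falls below ``min_identity``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .amplicon import AmpliconReference
from .simulate import SimRead

_NEG = -(10**9)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    table = str.maketrans("ACGTN", "TGCAN")
    return seq.upper().translate(table)[::-1]


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2
    min_identity: float = 0.6
    band: int = 64  # half-width around the seeded diagonal
    seed_k: int = 15


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-reference alignment (CIGAR over {M, I, D, S})."""

    read_id: str
    mapped: bool
    ref_offset: int
    strand: str
    cigar: tuple[tuple[str, int], ...]
    edit_distance: int
    aligned_identity: float
    score: int
    query_length: int

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def ref_end(self) -> int:
        return self.ref_offset + self.ref_span

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar) if self.cigar else "*"


@njit(cache=True)
def _banded_dp(q, r, d0, W, match, mismatch, gap_oe, gap_e):  # pragma: no cover
    m = q.shape[0]
    n = r.shape[0]
    width = 2 * W + 1
    NEG = np.int32(-(10**8))
    # rolling value rows; full uint8 pointer matrices for traceback
    Mp = np.full(width, NEG, dtype=np.int32)
    Xp = np.full(width, NEG, dtype=np.int32)
    Yp = np.full(width, NEG, dtype=np.int32)
    Mc = np.full(width, NEG, dtype=np.int32)
    Xc = np.full(width, NEG, dtype=np.int32)
    Yc = np.full(width, NEG, dtype=np.int32)
    ptrH = np.zeros((m + 1, width), dtype=np.uint8)   # argmax(M,X,Y)
    ptrH2 = np.zeros((m + 1, width), dtype=np.uint8)  # argmax(M,Y)
    ptrX = np.zeros((m + 1, width), dtype=np.uint8)   # 0 open, 1 extend
    ptrY = np.zeros((m + 1, width), dtype=np.uint8)

    jbase0 = d0 - W
    for k in range(width):
        j = jbase0 + k
        if 0 <= j <= n:
            Mp[k] = 0
    for i in range(1, m + 1):
        jbase = i + d0 - W
        klo = 0 if jbase >= 0 else -jbase
        khi = width - 1
        if jbase + khi > n:
            khi = n - jbase
        qa = q[i - 1]
        for k in range(width):
            Mc[k] = NEG
            Xc[k] = NEG
            Yc[k] = NEG
        for k in range(klo, khi + 1):
            j = jbase + k
            # Y: gap in reference (query consumed), from (i-1, k+1)
            yv = NEG
            yp = np.uint8(0)
            if k + 1 < width:
                hprev = Mp[k + 1]
                if Xp[k + 1] > hprev:
                    hprev = Xp[k + 1]
                if Yp[k + 1] > hprev:
                    hprev = Yp[k + 1]
                yv = hprev + gap_oe
                ye = Yp[k + 1] + gap_e
                if ye > yv:
                    yv = ye
                    yp = np.uint8(1)
                if yv < NEG:
                    yv = NEG
            Yc[k] = yv
            ptrY[i, k] = yp
            # M: diagonal from (i-1, k)
            mv = NEG
            if j >= 1:
                hd = Mp[k]
                if Xp[k] > hd:
                    hd = Xp[k]
                if Yp[k] > hd:
                    hd = Yp[k]
                ra = r[j - 1]
                if qa == ra and qa < 4:
                    mv = hd + match
                else:
                    mv = hd + mismatch
                if mv < NEG:
                    mv = NEG
            Mc[k] = mv
            # X: gap in query (reference consumed), from (i, k-1)
            xv = NEG
            xp = np.uint8(0)
            if k - 1 >= 0 and j >= 1:
                h2 = Mc[k - 1]
                if Yc[k - 1] > h2:
                    h2 = Yc[k - 1]
                xv = h2 + gap_oe
                xe = Xc[k - 1] + gap_e
                if xe > xv:
                    xv = xe
                    xp = np.uint8(1)
                if xv < NEG:
                    xv = NEG
            Xc[k] = xv
            ptrX[i, k] = xp
            # layer argmaxes (M preferred on ties, then X, then Y)
            best = mv
            arg = np.uint8(0)
            if xv > best:
                best = xv
                arg = np.uint8(1)
            if yv > best:
                best = yv
                arg = np.uint8(2)
            ptrH[i, k] = arg
            ptrH2[i, k] = np.uint8(0) if mv >= yv else np.uint8(2)
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp

    # terminal: free trailing reference gap; alignment may not end in X
    best = NEG
    bk = -1
    blayer = np.uint8(0)
    jbase = m + d0 - W
    for k in range(width):
        j = jbase + k
        if j < 0 or j > n:
            continue
        if Mp[k] > best:
            best = Mp[k]
            bk = k
            blayer = np.uint8(0)
        if Yp[k] > best:
            best = Yp[k]
            bk = k
            blayer = np.uint8(2)
    ops = np.zeros(m + n + 2, dtype=np.uint8)  # 0=M 1=I 2=D
    n_ops = 0
    n_match = 0
    if bk < 0 or best <= NEG // 2:
        return _NEG, -1, ops[:0], 0
    i = m
    k = bk
    layer = blayer
    while i > 0:
        j = i + d0 - W + k
        if layer == 0:
            ops[n_ops] = 0
            n_ops += 1
            if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                n_match += 1
            i -= 1
            layer = ptrH[i, k]
        elif layer == 2:
            ops[n_ops] = 1
            n_ops += 1
            opened = ptrY[i, k] == 0
            i -= 1
            k += 1
            if opened:
                layer = ptrH[i, k]
        else:
            ops[n_ops] = 2
            n_ops += 1
            opened = ptrX[i, k] == 0
            k -= 1
            if opened:
                layer = ptrH2[i, k]
    ref_start = i + d0 - W + k
    return int(best), ref_start, ops[:n_ops][::-1].copy(), n_match


class ReferenceIndex:
    """Exact k-mer index of the reference used to seed the band."""

    def __init__(self, reference: AmpliconReference, k: int = 15, max_hits: int = 4):
        self.reference = reference
        self.k = k
        self.codes = _encode(reference.sequence)
        self.index: dict[str, list[int]] = {}
        seq = reference.sequence.upper()
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            hits = self.index.setdefault(kmer, [])
            if len(hits) <= max_hits:
                hits.append(pos)
        self.max_hits = max_hits

    def diagonal_votes(self, seq: str) -> dict[int, int]:
        k = self.k
        votes: dict[int, int] = {}
        if len(seq) < k:
            return votes
        stride = max(1, (len(seq) - k) // 24)
        for qpos in range(0, len(seq) - k + 1, stride):
            hits = self.index.get(seq[qpos : qpos + k])
            if hits and len(hits) <= self.max_hits:
                for rpos in hits:
                    d = rpos - qpos
                    votes[d] = votes.get(d, 0) + 1
        return votes


def _best_diagonal(votes: dict[int, int]) -> tuple[int | None, int]:
    if not votes:
        return None, 0
    d = max(votes, key=lambda key: (votes[key], -abs(key)))
    return d, votes[d]


def _ops_to_cigar(ops: np.ndarray) -> tuple[tuple[str, int], ...]:
    if ops.size == 0:
        return ()
    names = "MID"
    bounds = np.flatnonzero(np.diff(ops)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [ops.size]))
    return tuple(
        (names[ops[s]], int(e - s)) for s, e in zip(starts, ends)
    )


def _run_dp(
    q: np.ndarray, r: np.ndarray, d0: int, W: int, scoring: Scoring
) -> tuple[int, int, np.ndarray, int]:
    return _banded_dp(
        q,
        r,
        np.int64(d0),
        np.int64(W),
        np.int64(scoring.match),
        np.int64(scoring.mismatch),
        np.int64(scoring.gap_open + scoring.gap_extend),
        np.int64(scoring.gap_extend),
    )


def align_read(
    read: SimRead | tuple[str, str],
    reference: AmpliconReference,
    scoring: Scoring | None = None,
    index: ReferenceIndex | None = None,
) -> AlignmentRecord:
    """Align one read (best of forward and reverse-complement).

    Ties between strands go to the forward strand.  The band is centred
    on the best-voted seed diagonal; reads without seed support fall back
    to an unbanded alignment on both strands.
    """
    if isinstance(read, tuple):
        read = SimRead(read[0], read[1], "")
    if not read.sequence:
        raise ValueError(f"{read.read_id}: empty read")
    scoring = scoring or Scoring()
    index = index or ReferenceIndex(reference, k=scoring.seed_k)
    r = index.codes
    q_f = _encode(read.sequence)
    q_r = _revcomp_codes(q_f)
    m, n = q_f.shape[0], r.shape[0]

    d_f, v_f = _best_diagonal(index.diagonal_votes(read.sequence))
    candidates: list[tuple[str, np.ndarray, int | None]] = []
    if v_f >= 6:  # decisive forward seed support
        candidates = [("+", q_f, d_f)]
    else:
        d_r, v_r = _best_diagonal(index.diagonal_votes(revcomp(read.sequence)))
        if d_f is not None and v_f >= 2 * max(v_r, 1):
            candidates = [("+", q_f, d_f)]
        elif d_r is not None and v_r >= 2 * max(v_f, 1):
            candidates = [("-", q_r, d_r)]
        else:
            if d_f is not None:
                candidates.append(("+", q_f, d_f))
            if d_r is not None:
                candidates.append(("-", q_r, d_r))
    if not candidates:  # no seed support at all: unbanded, both strands
        candidates = [("+", q_f, None), ("-", q_r, None)]

    best: tuple[int, int, np.ndarray, int, str] | None = None
    narrow = min(16, scoring.band)
    for strand, q, diag in candidates:
        if diag is None:
            d0, W = 0, max(m, n)  # unbanded
        else:
            d0, W = diag, narrow
        score, start, ops, n_match = _run_dp(q, r, d0, W, scoring)
        if (
            diag is not None
            and narrow < scoring.band
            and (ops.size == 0 or n_match / max(ops.size, 1) < 0.75)
        ):
            # drifted out of the narrow band: retry at the full band
            score, start, ops, n_match = _run_dp(q, r, d0, scoring.band, scoring)
        if score <= _NEG // 2:
            continue
        if (
            best is None
            or score > best[0]
            or (score == best[0] and (start, strand) < (best[1], best[4]))
        ):
            best = (score, start, ops, n_match, strand)

    if best is None:
        return AlignmentRecord(
            read.read_id, False, -1, "+", (), 0, 0.0, _NEG, m
        )
    score, start, ops, n_match, strand = best
    cigar = _ops_to_cigar(ops)
    cols = len(ops)
    identity = n_match / cols if cols else 0.0
    edit = cols - n_match
    mapped = identity >= scoring.min_identity
    return AlignmentRecord(
        read.read_id, mapped, int(start), strand, cigar, int(edit),
        float(identity), int(score), m,
    )


def align_reads(
    reads: Sequence[SimRead],
    reference: AmpliconReference,
    scoring: Scoring | None = None,
) -> list[AlignmentRecord]:
    scoring = scoring or Scoring()
    index = ReferenceIndex(reference, k=scoring.seed_k)
    return [align_read(rd, reference, scoring, index) for rd in reads]


# ---------------------------------------------------------------------------
# Coverage


@dataclass(frozen=True)
class CoverageProfile:
    depth: np.ndarray
    relative_depth: np.ndarray


def coverage_profile(
    records: Sequence[AlignmentRecord], reference: AmpliconReference
) -> CoverageProfile:
    """Per-offset depth over M/D-covered reference positions."""
    L = len(reference)
    diff = np.zeros(L + 1, dtype=np.int64)
    any_mapped = False
    for rec in records:
        if not rec.mapped:
            continue
        any_mapped = True
        diff[rec.ref_offset] += 1
        diff[min(rec.ref_end, L)] -= 1
    if not any_mapped:
        raise ValueError("no mapped reads: cannot compute coverage profile")
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(depth, depth / depth.max())


# ---------------------------------------------------------------------------
# SAM import / export (pysam)


def export_sam(
    records: Sequence[AlignmentRecord],
    reads: Sequence[SimRead],
    reference: AmpliconReference,
    path: str | Path,
) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference.name, "LN": len(reference)}],
    }
    by_id = {r.read_id: r for r in reads}
    opnum = {"M": 0, "I": 1, "D": 2, "S": 4}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            read = by_id.get(rec.read_id)
            seq = read.sequence if read else None
            qual = read.quality if read else None
            if seq is not None and rec.strand == "-":
                seq = revcomp(seq)
                qual = qual[::-1] if qual else None
            if rec.mapped:
                seg.flag = 16 if rec.strand == "-" else 0
                seg.reference_id = 0
                seg.reference_start = rec.ref_offset
                seg.mapping_quality = 60
                seg.cigartuples = [(opnum[op], n) for op, n in rec.cigar]
                seg.set_tag("NM", rec.edit_distance)
            else:
                seg.flag = 4
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            if seq:
                seg.query_sequence = seq
                if qual:
                    seg.query_qualities = pysam.qualitystring_to_array(qual)
            out.write(seg)


def import_sam(path: str | Path) -> list[AlignmentRecord]:
    import pysam

    opname = "MIDNSHP=X"
    records: list[AlignmentRecord] = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=True) as fh:
            for lineno, seg in enumerate(fh, start=1):
                if seg.is_unmapped:
                    records.append(
                        AlignmentRecord(
                            seg.query_name, False, -1, "+", (), 0, 0.0,
                            _NEG, seg.query_length or 0,
                        )
                    )
                    continue
                cigar = tuple(
                    (opname[op], n) for op, n in (seg.cigartuples or ())
                )
                bad = [op for op, _ in cigar if op not in "MIDS"]
                if bad:
                    raise ValueError(
                        f"{path}: record {lineno} ({seg.query_name}): "
                        f"unsupported CIGAR op(s) {bad}"
                    )
                nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
                cols = sum(n for op, n in cigar if op in "MID")
                identity = 1.0 - nm / cols if cols else 0.0
                records.append(
                    AlignmentRecord(
                        seg.query_name,
                        True,
                        seg.reference_start,
                        "-" if seg.is_reverse else "+",
                        cigar,
                        int(nm),
                        float(identity),
                        0,
                        seg.query_length or seg.infer_query_length() or 0,
                    )
                )
    except ValueError:
        raise
    except Exception as exc:  # pysam parse failures
        raise ValueError(f"{path}: malformed SAM ({exc})") from exc
    return records
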