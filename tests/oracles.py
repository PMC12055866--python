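"""Independent reference implementations used only as test oracles.

Everything here is written naively and independently of the package's
implementation paths: scalar dynamic programming, per-molecule event
simulation, explicit enumeration.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def global_gotoh(q: str, r: str, match: int, mismatch: int,
                 gap_open: int, gap_extend: int) -> float:
    """Plain scalar global affine-gap alignment score.

    A gap of length g costs gap_open + g * gap_extend.
    """
    m, n = len(q), len(r)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (ref consumed)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in ref (query consumed)
    M[0][0] = 0.0
    for j in range(1, n + 1):
        X[0][j] = gap_open + j * gap_extend
    for i in range(1, m + 1):
        Y[i][0] = gap_open + i * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if q[i - 1] == r[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend,
                X[i][j - 1] + gap_extend,
                Y[i][j - 1] + gap_open + gap_extend,
            )
            Y[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend,
                Y[i - 1][j] + gap_extend,
                X[i - 1][j] + gap_open + gap_extend,
            )
    return max(M[m][n], X[m][n], Y[m][n])


def semiglobal_oracle(q: str, r: str, match: int = 2, mismatch: int = -4,
                      gap_open: int = -4, gap_extend: int = -2) -> float:
    """Exhaustive semiglobal score: the best global alignment of the read
    against every reference substring (free reference end gaps)."""
    best = NEG
    n = len(r)
    for s in range(n + 1):
        for e in range(s, n + 1):
            score = global_gotoh(q, r[s:e], match, mismatch, gap_open, gap_extend)
            if score > best:
                best = score
    return best


# ---------------------------------------------------------------------------
# PCR chimera oracle: direct per-molecule event listing, no pooling


def pcr_oracle_chimeric_fraction(
    n0_per_hap: int,
    cycles: int,
    efficiency0: float,
    chimera_rate0: float,
    capacity: int,
    length: int,
    seed: int,
) -> float:
    rng = np.random.default_rng(seed)
    # each molecule is a list of (start, end, hap) segments
    pool = [[(0, length, 0)] for _ in range(n0_per_hap)]
    pool += [[(0, length, 1)] for _ in range(n0_per_hap)]
    for _ in range(cycles):
        size = len(pool)
        load = size / capacity
        e_c = efficiency0 * max(0.0, 1.0 - load)
        chi_c = chimera_rate0 * min(1.0, load)
        new = []
        for idx in range(size):
            if rng.random() >= e_c:
                continue
            if rng.random() < chi_c:
                bp = int(rng.integers(1, length))
                partner = int(rng.integers(0, size - 1))
                if partner >= idx:
                    partner += 1
                prefix = [
                    (s, min(e, bp), h) for s, e, h in pool[idx] if s < bp
                ]
                suffix = [
                    (max(s, bp), e, h)
                    for s, e, h in pool[partner]
                    if e > bp
                ]
                new.append(prefix + suffix)
            else:
                new.append(list(pool[idx]))
        pool.extend(new)
    chim = sum(1 for mol in pool if len({h for _, _, h in mol}) > 1)
    return chim / len(pool)


# ---------------------------------------------------------------------------
# Pairwise concordance oracle: explicit enumeration of both pairings


def concordance_oracle(
    pairs: list[tuple[str, str]],
    alleles_a: tuple[str, str],
    alleles_b: tuple[str, str],
) -> tuple[float, int]:
    """(prop_correct, n_informative) by explicitly scoring both perfect
    matchings over the raw per-read allele pairs."""
    informative = [
        (a, b)
        for a, b in pairs
        if a in alleles_a and b in alleles_b
    ]
    n = len(informative)
    if n == 0:
        return float("nan"), 0
    a1, a2 = alleles_a
    b1, b2 = alleles_b
    matchings = [
        {(a1, b1), (a2, b2)},
        {(a1, b2), (a2, b1)},
    ]
    best = max(
        sum(1 for p in informative if p in matching) for matching in matchings
    )
    return best / n, n


# ---------------------------------------------------------------------------
# Exhaustive phasing oracle: re-scan every read for every configuration


def phasing_oracle(
    rows: list[dict[str, str | None]],
    het_alleles: dict[str, tuple[str, str]],
    site_order: list[str],
) -> tuple[int, dict[str, str]]:
    """(best score, best H1 as a site->allele dict).

    Enumerates every phase configuration (the first site fixed to its
    alphabetically smaller allele) and re-scans every read for each;
    score ties are broken lexicographically on H1 in ``site_order``.
    """
    import itertools

    sites = list(site_order)
    pairs = {s: tuple(sorted(het_alleles[s])) for s in sites}
    best_score = -1
    best_h1: tuple[str, ...] | None = None
    for bits in itertools.product((0, 1), repeat=len(sites) - 1):
        choice = (0,) + bits
        h1 = tuple(pairs[s][c] for s, c in zip(sites, choice))
        h2 = tuple(pairs[s][1 - c] for s, c in zip(sites, choice))
        score = 0
        for row in rows:
            agree1 = agree2 = 0
            for si, s in enumerate(sites):
                base = row.get(s)
                if base is None or base not in pairs[s]:
                    continue
                if base == h1[si]:
                    agree1 += 1
                if base == h2[si]:
                    agree2 += 1
            score += max(agree1, agree2)
        if score > best_score or (score == best_score and h1 < best_h1):
            best_score = score
            best_h1 = h1
    return best_score, dict(zip(sites, best_h1))
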