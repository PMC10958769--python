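"""Independent brute-force oracles and small construction helpers.

Everything here is deliberately naive (per-position set arithmetic, cubic
dynamic programming) and shares no code with the package's vectorized
implementations, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def naive_window_counts(oligo: str, subject: str, start: int) -> tuple[int, int]:
    mm = nn = 0
    for j, osym in enumerate(oligo):
        ssym = subject[start + j]
        if ssym == "N":
            nn += 1
        elif not IUPAC_SETS[ssym] <= IUPAC_SETS[osym]:
            mm += 1
    return mm, nn


def naive_scan(oligo: str, subject: str, max_mm: int,
               max_n: int) -> list[tuple[int, int, int]]:
    """All (start, mismatches, n_positions) windows within the budgets."""
    out = []
    for start in range(len(subject) - len(oligo) + 1):
        mm, nn = naive_window_counts(oligo, subject, start)
        if mm <= max_mm and nn <= max_n:
            out.append((start, mm, nn))
    return out


def naive_identity(a: str, b: str) -> float:
    """Global alignment (match +1, mismatch -1, gap -2), plain Python DP.

    Traceback prefers diagonal, then up, then left; identity is identical
    aligned positions over the shorter input length.
    """
    n, m = len(a), len(b)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        S[0][j] = -2 * j
    for i in range(1, n + 1):
        S[i][0] = -2 * i
        for j in range(1, m + 1):
            sub = 1 if a[i - 1] == b[j - 1] else -1
            S[i][j] = max(S[i - 1][j - 1] + sub, S[i - 1][j] - 2, S[i][j - 1] - 2)
    i, j, matches = n, m, 0
    while i > 0 and j > 0:
        sub = 1 if a[i - 1] == b[j - 1] else -1
        if S[i][j] == S[i - 1][j - 1] + sub:
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif S[i][j] == S[i - 1][j] - 2:
            i -= 1
        else:
            j -= 1
    return matches / min(n, m)


def naive_greedy_cluster(named_seqs: list[tuple[str, str]],
                         cutoff: float) -> dict[str, str]:
    """Greedy incremental clustering; returns seq id -> centroid id."""
    pool = sorted(named_seqs, key=lambda t: (-len(t[1]), t[0]))
    assignment: dict[str, str] = {}
    while pool:
        (cid, cseq), rest = pool[0], pool[1:]
        assignment[cid] = cid
        remaining = []
        for sid, seq in rest:
            if naive_identity(cseq, seq) >= cutoff:
                assignment[sid] = cid
            else:
                remaining.append((sid, seq))
        pool = remaining
    return assignment


def random_iupac(rng: np.random.Generator, length: int,
                 degenerate_fraction: float = 0.15) -> str:
    """A random IUPAC string, mostly concrete bases with some ambiguity."""
    plain = list("ACGT")
    degen = list("RYSWKMBDHVN")
    out = []
    for _ in range(length):
        if rng.random() < degenerate_fraction:
            out.append(degen[rng.integers(0, len(degen))])
        else:
            out.append(plain[rng.integers(0, 4)])
    return "".join(out)


def random_dna(rng: np.random.Generator, length: int,
               n_fraction: float = 0.0) -> str:
    bases = "ACGT"
    out = [bases[rng.integers(0, 4)] for _ in range(length)]
    if n_fraction:
        k = round(n_fraction * length)
        for i in rng.choice(length, size=k, replace=False):
            out[i] = "N"
    return "".join(out)


def plant_site(rng: np.random.Generator, site: str, total_length: int,
               position: int, forbid_patterns: list[str],
               max_tries: int = 200) -> str:
    """A random sequence with ``site`` at ``position`` and no accidental
    occurrence of any pattern in ``forbid_patterns`` elsewhere (checked with
    the naive scanner at 0 mismatches / 0 N)."""
    for _ in range(max_tries):
        seq = list(random_dna(rng, total_length))
        seq[position:position + len(site)] = site
        seq = "".join(seq)
        ok = True
        for pat in forbid_patterns:
            hits = [s for s, _, _ in naive_scan(pat, seq, 0, 0)]
            if hits != ([position] if pat == site else []):
                ok = False
                break
        if ok:
            return seq
    raise RuntimeError("could not build a clean planted sequence")
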