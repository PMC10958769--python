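"""Naive brute-force matcher and random-sequence helpers for acceptance runs.

Independent of the package's vectorized scanner: per-position IUPAC set
arithmetic only, so agreement between the two routes is meaningful.
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


def naive_scan(oligo: str, subject: str, max_mm: int,
               max_n: int) -> list[tuple[int, int, int]]:
    out = []
    for start in range(len(subject) - len(oligo) + 1):
        mm = nn = 0
        for j, osym in enumerate(oligo):
            ssym = subject[start + j]
            if ssym == "N":
                nn += 1
            elif not IUPAC_SETS[ssym] <= IUPAC_SETS[osym]:
                mm += 1
        if mm <= max_mm and nn <= max_n:
            out.append((start, mm, nn))
    return out


def random_iupac(rng: np.random.Generator, length: int,
                 degenerate_fraction: float = 0.15) -> str:
    plain = list("ACGT")
    degen = list("RYSWKMBDHVN")
    return "".join(
        degen[rng.integers(0, len(degen))] if rng.random() < degenerate_fraction
        else plain[rng.integers(0, 4)]
        for _ in range(length))


def random_dna(rng: np.random.Generator, length: int,
               n_fraction: float = 0.0) -> str:
    bases = "ACGT"
    out = [bases[rng.integers(0, 4)] for _ in range(length)]
    if n_fraction:
        k = round(n_fraction * length)
        for i in rng.choice(length, size=k, replace=False):
            out[i] = "N"
    return "".join(out)
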