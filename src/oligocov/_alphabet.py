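"""IUPAC nucleotide alphabet: expansion sets, bitmasks, complements, normalization.

Each IUPAC symbol denotes a set of concrete bases. The 4-bit mask encoding
(A=1, C=2, G=4, T=8) makes the subset test used by the scanner a single
bitwise operation: set(x) is a subset of set(y) iff mask(x) & ~mask(y) == 0.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 1, 2, 4, 8

MASKS: dict[str, int] = {
    "A": A,
    "C": C,
    "G": G,
    "T": T,
    "R": A | G,
    "Y": C | T,
    "S": C | G,
    "W": A | T,
    "K": G | T,
    "M": A | C,
    "B": C | G | T,
    "D": A | G | T,
    "H": A | C | T,
    "V": A | C | G,
    "N": A | C | G | T,
}

N_MASK = MASKS["N"]

EXPANSIONS: dict[str, frozenset[str]] = {
    sym: frozenset(b for b in "ACGT" if MASKS[sym] & MASKS[b]) for sym in MASKS
}

COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "S": "S", "W": "W", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

IUPAC_SYMBOLS = frozenset(MASKS)

# byte -> mask lookup; 0 marks an invalid symbol
_ENCODE = np.zeros(256, dtype=np.uint8)
for _sym, _mask in MASKS.items():
    _ENCODE[ord(_sym)] = _mask

_STRIP = str.maketrans({"-": None, ".": None, " ": None, "\t": None, "\n": None, "\r": None})


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the IUPAC nucleotide alphabet."""


def validate(seq: str, *, context: str = "sequence") -> str:
    bad = set(seq) - IUPAC_SYMBOLS
    if bad:
        raise AlphabetError(
            f"{context} contains non-IUPAC symbol(s): {sorted(bad)!r}"
        )
    return seq


def normalize(seq: str) -> str:
    """Uppercase, RNA U -> DNA T, strip alignment gaps ('-', '.') and whitespace.

    Idempotent; raises :class:`AlphabetError` if a non-IUPAC symbol remains.
    """
    out = seq.upper().replace("U", "T").translate(_STRIP)
    return validate(out)


def encode(seq: str) -> np.ndarray:
    """Encode an IUPAC string as a uint8 array of 4-bit expansion masks."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[arr]
    if (codes == 0).any():
        validate(seq)  # raises with a readable message
    return codes


def reverse_complement(seq: str) -> str:
    """Reverse complement under the full IUPAC complement table."""
    try:
        return "".join(COMPLEMENT[s] for s in reversed(seq))
    except KeyError:
        validate(seq)
        raise
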