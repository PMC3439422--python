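"""Low-level nucleotide sequence helpers shared across modules.

Sequences are plain Python strings over A/C/G/T (DNA sense) or A/C/G/U
(RNA sense).  Numeric encoding uses A=0, C=1, G=2, T/U=3; N and anything
else encodes as 4, which never matches during alignment.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    ENCODE[ord(_c)] = _i
    ENCODE[ord(_c.lower())] = _i
ENCODE[ord("U")] = 3
ENCODE[ord("u")] = 3

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement (U is treated as T)."""
    return seq.translate(_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array (A=0, C=1, G=2, T/U=3, other=4)."""
    return ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DECODE[np.minimum(arr, 4)].tobytes().decode("ascii")


def hamming_leq(a: str, b: str, limit: int) -> int:
    """Hamming distance of equal-length strings with early exit.

    Returns the distance if it is <= limit, otherwise limit + 1.
    """
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping occurrence count of needle in haystack."""
    n = 0
    i = haystack.find(needle)
    while i >= 0:
        n += 1
        i = haystack.find(needle, i + 1)
    return n
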