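"""Low-level DNA utilities: complementation, Hamming distance, sliding scans.

Coordinates are 0-based half-open on the plus strand throughout the package.
The naive Hamming sliding scan is the reference matcher for both repeat
detection and protospacer mapping; it is vectorised with numpy but remains
bit-identical to a position-by-position scan.
"""
from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i


class SequenceError(ValueError):
    """Raised for sequences outside the A/C/G/T/N alphabet."""


def _check_alphabet(seq: str) -> None:
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise SequenceError(f"non-DNA characters in sequence: {bad}")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}.

    An involution: ``reverse_complement(reverse_complement(x)) == x``.
    """
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3, N=4)."""
    _check_alphabet(seq)
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def hamming_scan(text, query) -> np.ndarray:
    """Mismatch count of ``query`` against every window of ``text``.

    Returns an int32 array of length ``len(text) - len(query) + 1`` (empty if
    the query is longer than the text).  Accepts strings or pre-encoded uint8
    arrays.  N is its own symbol: it matches only N.
    """
    t = encode(text) if isinstance(text, str) else text
    q = encode(query) if isinstance(query, str) else query
    n, m = t.size, q.size
    if m == 0:
        raise ValueError("empty query")
    if m > n:
        return np.zeros(0, dtype=np.int32)
    out = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        out += t[j : j + n - m + 1] != q[j]
    return out


def random_dna(rng: np.random.Generator, length: int, gc_content: float) -> str:
    """I.i.d. random DNA at the given GC fraction (A/T and C/G equiprobable)."""
    if not 0.0 < gc_content < 1.0:
        raise ValueError(f"gc_content must be in (0, 1), got {gc_content}")
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(bases)
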