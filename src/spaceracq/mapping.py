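"""Protospacer mapping: locate spacers on reference replicons, both strands.

Strand convention: '+' means the spacer equals the plus-strand slice
``replicon.seq[start:end]``; '-' means the spacer equals the reverse
complement of that slice.  Coordinates are always reported on the plus
strand, 0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import encode, hamming_scan, reverse_complement

REPLICON_KINDS = ("host", "plasmid", "virus")

#: replicon-kind preference when mismatch counts tie (most-mobile first)
DEFAULT_PRIORITY = ("virus", "plasmid", "host")

#: kinds treated as circular DNA unless stated otherwise
DEFAULT_CIRCULAR_KINDS = frozenset({"plasmid", "virus"})


@dataclass
class Replicon:
    """A named reference sequence with a kind tag (host/plasmid/virus)."""

    id: str
    kind: str
    seq: str
    circular: bool = False
    _enc: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.kind not in REPLICON_KINDS:
            raise ValueError(f"unknown replicon kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def enc(self) -> np.ndarray:
        """Cached uint8 encoding of the plus strand."""
        if self._enc is None or self._enc.size != len(self.seq):
            self._enc = encode(self.seq)
        return self._enc


@dataclass(frozen=True)
class ProtospacerHit:
    spacer_id: str
    replicon_id: str
    replicon_kind: str
    start: int
    end: int
    strand: str  # '+' or '-'
    n_mismatches: int


def map_spacer(
    spacer: str,
    replicons,
    max_mismatch: int = 2,
    spacer_id: str = "",
) -> list[ProtospacerHit]:
    """All Hamming matches of a spacer on every replicon, both strands.

    Exact hits are listed before inexact; within each group the order is
    (replicon id, start, strand) with '+' before '-'.
    """
    if len(spacer) < 10:
        raise ValueError("spacer shorter than 10 nt cannot be mapped reliably")
    hits: list[ProtospacerHit] = []
    rc = reverse_complement(spacer)
    m = len(spacer)
    for rep in replicons:
        for strand, query in (("+", spacer), ("-", rc)):
            mm = hamming_scan(rep.enc, encode(query))
            for start in np.flatnonzero(mm <= max_mismatch):
                start = int(start)
                hits.append(
                    ProtospacerHit(
                        spacer_id=spacer_id,
                        replicon_id=rep.id,
                        replicon_kind=rep.kind,
                        start=start,
                        end=start + m,
                        strand=strand,
                        n_mismatches=int(mm[start]),
                    )
                )
    hits.sort(
        key=lambda h: (h.n_mismatches > 0, h.replicon_id, h.start, h.strand != "+")
    )
    return hits


def select_best_hit(
    hits: list[ProtospacerHit],
    priority=DEFAULT_PRIORITY,
) -> tuple[str, ProtospacerHit | None]:
    """Pick the single best hit, or declare the spacer ambiguous/unmapped.

    Best = fewest mismatches; ties broken by replicon-kind priority; any
    remaining tie makes the spacer 'ambiguous' (excluded from PAM
    classification but still counted in reports).

    Returns ``(status, hit)`` with status in {'best', 'ambiguous', 'unmapped'};
    hit is None unless status == 'best'.
    """
    if not hits:
        return "unmapped", None
    best_mm = min(h.n_mismatches for h in hits)
    pool = [h for h in hits if h.n_mismatches == best_mm]
    rank = {k: i for i, k in enumerate(priority)}
    best_rank = min(rank.get(h.replicon_kind, len(rank)) for h in pool)
    pool = [h for h in pool if rank.get(h.replicon_kind, len(rank)) == best_rank]
    if len(pool) > 1:
        return "ambiguous", None
    return "best", pool[0]
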