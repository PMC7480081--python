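"""Parsing leader-proximal CRISPR amplicons into repeat-spacer units.

Each sequenced clone is one amplicon: leader, then alternating repeats and
spacers.  Newly acquired spacers form a contiguous prefix at the leader end;
parsing anchors the observed spacer list on the first parental spacer and
everything before the anchor is called new.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import encode, hamming, hamming_scan, reverse_complement

MIN_SPACER_LEN = 10
MAX_SPACER_LEN = 80


class ArrayParseError(ValueError):
    """A clone that cannot be interpreted against the parental array."""


class UnanchoredError(ArrayParseError):
    """No spacer matches the first parental spacer."""


class RearrangedError(ArrayParseError):
    """Parental spacer order violated after the anchor."""


@dataclass(frozen=True)
class CRISPRLocus:
    """Leader + repeat + ordered parental spacers (leader-proximal first).

    Defines what "new spacer" means: anything observed before the first
    parental spacer in a clone's array.
    """

    leader_seq: str
    repeat_seq: str
    parental_spacers: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "parental_spacers", tuple(self.parental_spacers))
        if len(self.repeat_seq) < 18:
            raise ValueError("repeat must be at least 18 nt")
        if not self.parental_spacers:
            raise ValueError("parental spacer list is empty")
        for sp in self.parental_spacers:
            if self.repeat_seq in sp:
                raise ValueError("repeat occurs inside a parental spacer")

    @property
    def parental_array(self) -> str:
        """Full parental amplicon: leader + R + (spacer + R) for each spacer."""
        r = self.repeat_seq
        return self.leader_seq + r + "".join(s + r for s in self.parental_spacers)


@dataclass(frozen=True)
class SpacerRecord:
    clone_id: str
    position_from_leader: int  # 0-based; 0 = leader-most
    seq: str
    is_new: bool


@dataclass
class ParsedClone:
    clone_id: str
    status: str  # ok | unparseable | unanchored | rearranged
    spacers: list[SpacerRecord] = field(default_factory=list)
    multiplicity: int = 0
    reason: str = ""


def find_repeats(amplicon_seq: str, repeat_seq: str, max_mismatch: int = 2):
    """Greedy left-to-right non-overlapping Hamming matches of the repeat.

    Scans every start position in order; a match (Hamming distance <=
    ``max_mismatch``) consumes its span so overlapping candidates further
    right are skipped.  Returns ``[start, end)`` intervals sorted by start.
    A repeat longer than the amplicon yields an empty list.
    """
    if max_mismatch < 0 or max_mismatch > len(repeat_seq) // 6:
        raise ValueError(
            f"max_mismatch must be in [0, {len(repeat_seq) // 6}] for a "
            f"{len(repeat_seq)}-nt repeat"
        )
    m = len(repeat_seq)
    mm = hamming_scan(encode(amplicon_seq), encode(repeat_seq))
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < mm.size:
        if mm[i] <= max_mismatch:
            intervals.append((i, i + m))
            i += m
        else:
            i += 1
    return intervals


def extract_spacers(amplicon_seq: str, repeat_intervals):
    """Inter-repeat segments in amplicon order.

    Segments shorter than 10 nt or longer than 80 nt are excluded from
    downstream mapping and returned separately with a reason.  Sequence
    before the first repeat (leader) and after the last repeat (primer
    tail) is ignored.

    Returns ``(spacers, flagged)`` where flagged is a list of
    ``(segment_index, seq, reason)``.
    """
    if len(repeat_intervals) < 2:
        raise ArrayParseError("fewer than two repeats: clone unparseable")
    spacers: list[str] = []
    flagged: list[tuple[int, str, str]] = []
    for k in range(len(repeat_intervals) - 1):
        seg = amplicon_seq[repeat_intervals[k][1] : repeat_intervals[k + 1][0]]
        if len(seg) < MIN_SPACER_LEN:
            flagged.append((k, seg, f"segment too short ({len(seg)} nt)"))
        elif len(seg) > MAX_SPACER_LEN:
            flagged.append((k, seg, f"segment too long ({len(seg)} nt)"))
        else:
            spacers.append(seg)
    return spacers, flagged


def _matches(a: str, b: str, max_mismatch: int) -> bool:
    return len(a) == len(b) and hamming(a, b) <= max_mismatch


def call_new_spacers(spacers, locus: CRISPRLocus, anchor_mismatch: int = 2):
    """Split an ordered spacer list into new spacers and the parental tail.

    Finds the first index ``i`` where ``spacers[i]`` matches the first
    parental spacer within ``anchor_mismatch`` Hamming distance; the
    remaining spacers must then match the parental list in order (the
    amplicon may stop early).  Returns ``(new_spacers, multiplicity)`` with
    ``multiplicity == i``.

    Raises :class:`UnanchoredError` if no anchor is found and
    :class:`RearrangedError` if the tail violates parental order.
    """
    spacers = list(spacers)
    parental = locus.parental_spacers
    anchor = None
    for i, sp in enumerate(spacers):
        if _matches(sp, parental[0], anchor_mismatch):
            anchor = i
            break
    if anchor is None:
        raise UnanchoredError("no spacer matches the first parental spacer")
    tail = spacers[anchor:]
    if len(tail) > len(parental):
        raise RearrangedError("more spacers after anchor than parental spacers")
    for k, sp in enumerate(tail):
        if not _matches(sp, parental[k], anchor_mismatch):
            raise RearrangedError(f"parental order violated at position {k}")
    return spacers[:anchor], anchor


def parse_amplicon(
    clone_id: str,
    amplicon_seq: str,
    locus: CRISPRLocus,
    max_mismatch: int = 2,
    anchor_mismatch: int = 2,
    auto_orient: bool = True,
) -> ParsedClone:
    """Full per-clone parse: repeats -> spacers -> new-spacer call.

    If fewer than two repeats are found and ``auto_orient`` is set, the
    reverse complement of the amplicon is tried before giving up.
    """
    seq = amplicon_seq.upper()
    intervals = find_repeats(seq, locus.repeat_seq, max_mismatch)
    if len(intervals) < 2 and auto_orient:
        rc = reverse_complement(seq)
        rc_intervals = find_repeats(rc, locus.repeat_seq, max_mismatch)
        if len(rc_intervals) >= 2:
            seq, intervals = rc, rc_intervals
    if len(intervals) < 2:
        return ParsedClone(clone_id, "unparseable", reason="fewer than two repeats")
    spacers, _flagged = extract_spacers(seq, intervals)
    try:
        new, multiplicity = call_new_spacers(spacers, locus, anchor_mismatch)
    except UnanchoredError as e:
        return ParsedClone(clone_id, "unanchored", reason=str(e))
    except RearrangedError as e:
        return ParsedClone(clone_id, "rearranged", reason=str(e))
    records = [
        SpacerRecord(clone_id, pos, sp, pos < multiplicity)
        for pos, sp in enumerate(spacers)
    ]
    return ParsedClone(clone_id, "ok", records, multiplicity)


def parse_amplicons(amplicons, locus: CRISPRLocus, **kwargs) -> list[ParsedClone]:
    """Parse ``(clone_id, seq)`` pairs; one :class:`ParsedClone` each."""
    return [parse_amplicon(cid, seq, locus, **kwargs) for cid, seq in amplicons]
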