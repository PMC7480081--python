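"""PAM extraction and integration-mode classification.

Subtype I-A adaptation in Sulfolobus selects protospacers next to a 5'-CCN
motif.  Relative to the spacer as stored in the array, five mutually
exclusive outcomes are distinguished:

* ``canonical`` - 5'-CCN immediately upstream of the protospacer;
* ``flip``      - the spacer was inserted inverted, so the CCN appears as a
  3'-NGG immediately downstream in the stored orientation;
* ``slip``      - the CC (or its mirrored GG) sits a few nucleotides away
  from the canonical position, i.e. the spacer boundary slipped relative to
  the PAM;
* ``mismatch``  - the upstream -3..-1 triplet is CDN or DCN with
  D in {A, T, G}: exactly one of the two Cs retained;
* ``other``     - none of the above (also the fallback for events too close
  to the end of a linear replicon to read a full flank).

Classification is first-match-wins in the order above, which makes the
classes exclusive and exhaustive.
"""
from __future__ import annotations

from dataclasses import dataclass

from .mapping import ProtospacerHit, Replicon
from .sequences import reverse_complement

PAM_CLASSES = ("canonical", "flip", "slip", "mismatch", "other")

DEFAULT_FLANK_LEN = 6  # minimum to evaluate slip offsets up to +/-3
DEFAULT_SLIP_OFFSETS = (-3, -2, -1, 1, 2, 3)


@dataclass(frozen=True)
class FlankPair:
    """Protospacer flanks in spacer (stored) orientation.

    ``up`` ends immediately 5' of the protospacer, ``down`` starts
    immediately 3' of it.  For minus-strand hits both are taken from the
    reverse complement so "up" is always the spacer-orientation 5' side.
    ``edge`` marks events too close to a linear replicon end for full
    flanks; they classify as "other".
    """

    up: str
    down: str
    edge: bool = False


@dataclass(frozen=True)
class PamCall:
    pam_class: str
    slip_offset: int | None = None

    def __post_init__(self):
        if self.pam_class not in PAM_CLASSES:
            raise ValueError(f"unknown PAM class {self.pam_class!r}")


def extract_flanks(
    hit: ProtospacerHit,
    replicon: Replicon,
    up_len: int = DEFAULT_FLANK_LEN,
    down_len: int = DEFAULT_FLANK_LEN,
    circular: bool | None = None,
) -> FlankPair:
    """Flanking sequence of a hit, oriented with the stored spacer.

    Plus-strand hit: up = seq[start-U:start], down = seq[end:end+D].
    Minus-strand hit: up = rc(seq[end:end+U]), down = rc(seq[start-D:start]).
    Circular replicons wrap around the origin; on linear replicons a flank
    crossing a boundary yields an edge-flagged pair.
    """
    seq = replicon.seq
    n = len(seq)
    wrap = replicon.circular if circular is None else circular

    def slice_(lo: int, hi: int) -> str | None:
        if 0 <= lo and hi <= n:
            return seq[lo:hi]
        if not wrap:
            return None
        return "".join(seq[i % n] for i in range(lo, hi))

    if hit.strand == "+":
        up = slice_(hit.start - up_len, hit.start)
        down = slice_(hit.end, hit.end + down_len)
    else:
        up_src = slice_(hit.end, hit.end + up_len)
        down_src = slice_(hit.start - down_len, hit.start)
        up = reverse_complement(up_src) if up_src is not None else None
        down = reverse_complement(down_src) if down_src is not None else None
    if up is None or down is None:
        return FlankPair(up or "", down or "", edge=True)
    return FlankPair(up, down)


def _up_base(up: str, pos: int) -> str | None:
    """Base at upstream position ``pos`` (-1 = nearest to the protospacer)."""
    idx = len(up) + pos
    return up[idx] if 0 <= idx < len(up) else None


def _down_base(down: str, pos: int) -> str | None:
    """Base at downstream position ``pos`` (+1 = nearest to the protospacer)."""
    idx = pos - 1
    return down[idx] if 0 <= idx < len(down) else None


def classify_pam(
    flanks: FlankPair,
    slip_offsets=DEFAULT_SLIP_OFFSETS,
) -> PamCall:
    """Assign one of the five integration classes; first matching rule wins.

    Slip is checked at each offset delta (sorted by |delta|, positive first)
    as CC at upstream positions (-3+delta, -2+delta) or GG at downstream
    positions (+2+delta, +3+delta), only when both positions lie inside the
    respective flank.  N never matches C or G, so ambiguous bases cannot
    produce canonical/flip/slip calls.
    """
    if flanks.edge:
        return PamCall("other")
    up, down = flanks.up, flanks.down
    # 1. canonical: 5'-CCN immediately upstream
    if _up_base(up, -3) == "C" and _up_base(up, -2) == "C":
        return PamCall("canonical")
    # 2. flip: 3'-NGG immediately downstream
    if _down_base(down, 2) == "G" and _down_base(down, 3) == "G":
        return PamCall("flip")
    # 3. slip: CC/GG shifted by delta
    for delta in sorted((d for d in slip_offsets if d != 0), key=lambda d: (abs(d), -d)):
        if (
            _up_base(up, -3 + delta) == "C"
            and _up_base(up, -2 + delta) == "C"
            and -3 + delta <= -1
            and -2 + delta <= -1
        ):
            return PamCall("slip", delta)
        if (
            _down_base(down, 2 + delta) == "G"
            and _down_base(down, 3 + delta) == "G"
            and 2 + delta >= 1
        ):
            return PamCall("slip", delta)
    # 4. mismatch: CDN or DCN upstream, D in {A,T,G}
    b3, b2 = _up_base(up, -3), _up_base(up, -2)
    if b3 is not None and b2 is not None:
        if (b3 == "C" and b2 in "ATG") or (b3 in "ATG" and b2 == "C"):
            return PamCall("mismatch")
    # 5. residual
    return PamCall("other")
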