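"""Ground-truth simulator for leader-proximal spacer-acquisition amplicons.

Emulates the wet-lab assay: a host strain carrying a plasmid and/or infected
by a virus acquires new spacers at the leader end of its CRISPR array; the
leader-proximal region is PCR-amplified and individual clones are Sanger
sequenced.  The generator produces synthetic replicons (host chromosome,
plasmid, virus), a parental CRISPR locus, and per-clone amplicons with 0-4
planted repeat-spacer insertions, together with a truth table naming each
event's source coordinates, strand and integration mode.

Planting strategy: protospacer sites are sampled uniformly on the chosen
replicon, then the 6-nt flanks around the site are rewritten (in the stored
spacer orientation) until they satisfy exactly the requested integration
class under the classifier's rule priority.  Flank edits never overlap a
previously planted event, and every planted spacer is verified to map
uniquely (within the default mapping tolerance) so that mode and source
labels are unambiguous ground truth.

A single RNG stream, seeded once, drives every draw in documented order:
replicons (sorted by kind), locus (parental spacers in order), then clones
in order with events within a clone leader-first.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .arrays import CRISPRLocus
from .mapping import DEFAULT_CIRCULAR_KINDS, Replicon
from .pam import DEFAULT_SLIP_OFFSETS, FlankPair, classify_pam
from .sequences import encode, hamming_scan, random_dna, reverse_complement

#: genus-typical 24-nt direct repeat used as the default
DEFAULT_REPEAT = "GATAATCTCTTATAGAATTGAAAG"

#: AT-rich default leader (integration happens at its downstream edge)
DEFAULT_LEADER = (
    "ATTTAATTTCAAATATTTTTAAAGTATTTTAAATTATAAATTTCATAAAA"
    "TTTATTTAAATTTTAATAAATATTTTATT"
)

FLANK_LEN = 6
_PLACEMENT_ATTEMPTS = 200
_FLANK_ATTEMPTS = 2000

_DECODE = np.array(list("ACGTN"))


class GenerationError(RuntimeError):
    """Raised when a requested event cannot be planted."""


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _default_replicon_lengths():
    return {"host": 50000, "plasmid": 8000, "virus": 20000}


def _default_multiplicity_weights():
    # clone counts of the virus-infection condition: 57/20/13/1 insertions
    return {0: 0.0, 1: 0.63, 2: 0.22, 3: 0.14, 4: 0.01}


def _default_mode_weights():
    # class frequencies of the virus-infection condition
    return {
        "canonical": 0.565,
        "flip": 0.364,
        "slip": 0.043,
        "mismatch": 0.007,
        "other": 0.021,
    }


def _default_source_weights():
    return {"virus": 1.0}


@dataclass
class GeneratorConfig:
    seed: int = 0
    replicon_lengths: dict = field(default_factory=_default_replicon_lengths)
    gc_content: float = 0.38
    n_clones: int = 100
    multiplicity_weights: dict = field(default_factory=_default_multiplicity_weights)
    mode_weights: dict = field(default_factory=_default_mode_weights)
    source_weights: dict = field(default_factory=_default_source_weights)
    spacer_length_range: tuple[int, int] = (34, 44)
    slip_offsets: tuple[int, ...] = DEFAULT_SLIP_OFFSETS
    error_rate: float = 0.0
    repeat_seq: str = DEFAULT_REPEAT
    leader_seq: str = DEFAULT_LEADER
    n_parental_spacers: int = 5

    def validate(self) -> None:
        for name, weights in (
            ("multiplicity_weights", self.multiplicity_weights),
            ("mode_weights", self.mode_weights),
            ("source_weights", self.source_weights),
        ):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} sum to {total}, expected 1")
            if any(w < 0 for w in weights.values()):
                raise ConfigError(f"{name} contain a negative weight")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigError(f"gc_content must be in (0, 1), got {self.gc_content}")
        lo, hi = self.spacer_length_range
        if lo < 10 or hi < lo:
            raise ConfigError(f"bad spacer_length_range {self.spacer_length_range}")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if any(length <= 0 for length in self.replicon_lengths.values()):
            raise ConfigError("replicon lengths must be positive")
        if self.n_clones < 0 or self.n_parental_spacers < 1:
            raise ConfigError("n_clones must be >= 0 and n_parental_spacers >= 1")
        bad_modes = set(self.mode_weights) - {
            "canonical",
            "flip",
            "slip",
            "mismatch",
            "other",
        }
        if bad_modes:
            raise ConfigError(f"unknown modes in mode_weights: {sorted(bad_modes)}")


@dataclass(frozen=True)
class TruthRecord:
    clone_id: str
    event_index: int  # 0 = leader-most (newest)
    spacer_seq: str
    source_replicon_id: str
    source_start: int  # plus-strand, 0-based half-open
    source_end: int
    strand: str  # orientation of the match relative to the stored spacer
    planted_mode: str
    slip_offset: int | None


def generate_replicons(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[Replicon]:
    """One synthetic replicon per configured kind, i.i.d. bases at the set GC.

    Deterministic given the seed; kinds are generated in sorted order.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    replicons = []
    for kind in sorted(config.replicon_lengths):
        seq = random_dna(rng, config.replicon_lengths[kind], config.gc_content)
        replicons.append(
            Replicon(
                id=f"{kind}:synthetic_{kind}",
                kind=kind,
                seq=seq,
                circular=kind in DEFAULT_CIRCULAR_KINDS,
            )
        )
    return replicons


def generate_locus(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> CRISPRLocus:
    """Parental locus: configured leader/repeat plus random parental spacers.

    Spacers are resampled if they accidentally contain a near-copy of the
    repeat (which would break array parsing).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.spacer_length_range
    spacers = []
    for _ in range(config.n_parental_spacers):
        for _attempt in range(_PLACEMENT_ATTEMPTS):
            sp = random_dna(rng, int(rng.integers(lo, hi + 1)), config.gc_content)
            if not _contains_near_repeat(sp, config.repeat_seq):
                spacers.append(sp)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise GenerationError("could not draw a repeat-free parental spacer")
    return CRISPRLocus(config.leader_seq, config.repeat_seq, tuple(spacers))


def _contains_near_repeat(seq, repeat: str, max_mismatch: int = 2) -> bool:
    mm = hamming_scan(seq, repeat)
    return bool(mm.size) and int(mm.min()) <= max_mismatch


def _sample_flanks(rng, mode, slip_offsets):
    """Random 6+6-nt flank pair whose classification equals ``mode``.

    Constructive placement of the class motif followed by rejection against
    the full rule priority, so the planted label is unambiguous.
    Returns (up, down, slip_offset).
    """
    bases = np.array(list("ACGT"))
    for _ in range(_FLANK_ATTEMPTS):
        up = list(rng.choice(bases, size=FLANK_LEN))
        down = list(rng.choice(bases, size=FLANK_LEN))
        offset = None
        if mode == "canonical":
            up[FLANK_LEN - 3] = "C"
            up[FLANK_LEN - 2] = "C"
        elif mode == "flip":
            down[1] = "G"
            down[2] = "G"
        elif mode == "slip":
            choices = []
            for d in slip_offsets:
                if d == 0:
                    continue
                if -FLANK_LEN <= -3 + d and -2 + d <= -1:
                    choices.append((d, "up"))
                if 2 + d >= 1 and 3 + d <= FLANK_LEN:
                    choices.append((d, "down"))
            if not choices:
                raise GenerationError("no representable slip offset in flanks")
            offset, side = choices[int(rng.integers(len(choices)))]
            if side == "up":
                up[FLANK_LEN + (-3 + offset)] = "C"
                up[FLANK_LEN + (-2 + offset)] = "C"
            else:
                down[2 + offset - 1] = "G"
                down[3 + offset - 1] = "G"
        elif mode == "mismatch":
            d_base = "ATG"[int(rng.integers(3))]
            if rng.integers(2):
                up[FLANK_LEN - 3], up[FLANK_LEN - 2] = "C", d_base
            else:
                up[FLANK_LEN - 3], up[FLANK_LEN - 2] = d_base, "C"
        call = classify_pam(FlankPair("".join(up), "".join(down)), slip_offsets)
        if call.pam_class == mode and (mode != "slip" or call.slip_offset == offset):
            return "".join(up), "".join(down), call.slip_offset
    raise GenerationError(f"could not sample flanks for mode {mode!r}")


def _count_global_hits(spacer: str, enc_by_id, max_mismatch: int = 2) -> int:
    """Hamming matches of a spacer across all replicons, both strands."""
    total = 0
    rc = reverse_complement(spacer)
    q_fwd, q_rev = encode(spacer), encode(rc)
    for enc in enc_by_id.values():
        for q in (q_fwd, q_rev):
            mm = hamming_scan(enc, q)
            total += int((mm <= max_mismatch).sum())
    return total


def plant_events(replicons, locus: CRISPRLocus, config: GeneratorConfig, rng=None):
    """Plant acquisition events and build per-clone amplicons.

    Returns ``(amplicons, truth, edited_replicons)`` where amplicons is a
    list of ``(clone_id, sequence)``.  The returned replicons carry the
    flank rewrites and are the reference set all downstream stages must map
    against.  Substitution errors (``config.error_rate``) are applied to
    the amplicons last; the truth table stores error-free sequences.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if _contains_near_repeat(locus.leader_seq, locus.repeat_seq):
        raise GenerationError("leader contains a near-copy of the repeat")

    enc_by_id = {r.id: r.enc.copy() for r in replicons}
    rep_by_kind = {r.kind: r for r in replicons}
    occupied: dict[str, list[tuple[int, int]]] = {r.id: [] for r in replicons}

    mult_keys = sorted(config.multiplicity_weights)
    mult_p = np.array([float(config.multiplicity_weights[k]) for k in mult_keys])
    mode_keys = sorted(config.mode_weights)
    mode_p = np.array([float(config.mode_weights[k]) for k in mode_keys])
    src_keys = sorted(config.source_weights)
    src_p = np.array([float(config.source_weights[k]) for k in src_keys])
    for kind in src_keys:
        if config.source_weights[kind] > 0 and kind not in rep_by_kind:
            raise ConfigError(f"source kind {kind!r} has no generated replicon")

    truth: list[TruthRecord] = []
    amplicons: list[tuple[str, str]] = []
    width = max(4, len(str(max(config.n_clones - 1, 0))))

    for c in range(config.n_clones):
        clone_id = f"clone{c:0{width}d}"
        m = int(mult_keys[int(rng.choice(len(mult_keys), p=mult_p))])
        new_spacers: list[str] = []
        for e in range(m):
            mode = mode_keys[int(rng.choice(len(mode_keys), p=mode_p))]
            kind = src_keys[int(rng.choice(len(src_keys), p=src_p))]
            rep = rep_by_kind[kind]
            spacer, rec = _plant_one(
                rng, clone_id, e, mode, rep, enc_by_id, occupied, locus, config
            )
            new_spacers.append(spacer)
            truth.append(rec)
        spacer_chain = new_spacers + list(locus.parental_spacers)
        r = locus.repeat_seq
        amplicon = locus.leader_seq + r + "".join(s + r for s in spacer_chain)
        amplicons.append((clone_id, amplicon))

    if config.error_rate > 0:
        amplicons = [
            (cid, _mutate(rng, seq, config.error_rate)) for cid, seq in amplicons
        ]

    edited = [
        replace(r, seq="".join(_DECODE[enc_by_id[r.id]]), _enc=None)
        for r in replicons
    ]
    # final sanity pass: every planted spacer must still map uniquely
    final_enc = {r.id: r.enc for r in edited}
    for rec in truth:
        if _count_global_hits(rec.spacer_seq, final_enc) != 1:
            raise GenerationError(
                f"planted spacer for {rec.clone_id} lost uniqueness after edits"
            )
    return amplicons, truth, edited


def _plant_one(rng, clone_id, event_index, mode, rep, enc_by_id, occupied, locus, config):
    lo, hi = config.spacer_length_range
    arr = enc_by_id[rep.id]
    n = arr.size
    for _attempt in range(_PLACEMENT_ATTEMPTS):
        length = int(rng.integers(lo, hi + 1))
        if n < length + 2 * FLANK_LEN + 2:
            raise GenerationError(
                f"replicon {rep.id} too short for a {length}-nt protospacer"
            )
        start = int(rng.integers(FLANK_LEN, n - length - FLANK_LEN + 1))
        end = start + length
        window = (start - FLANK_LEN, end + FLANK_LEN)
        if any(a < window[1] and window[0] < b for a, b in occupied[rep.id]):
            continue
        strand = "+" if rng.integers(2) else "-"
        up, down, slip_offset = _sample_flanks(rng, mode, config.slip_offsets)
        # write flanks in stored-spacer orientation
        saved = arr[window[0] : window[1]].copy()
        if strand == "+":
            arr[start - FLANK_LEN : start] = encode(up)
            arr[end : end + FLANK_LEN] = encode(down)
        else:
            arr[end : end + FLANK_LEN] = encode(reverse_complement(up))
            arr[start - FLANK_LEN : start] = encode(reverse_complement(down))
        slice_seq = "".join(_DECODE[arr[start:end]])
        spacer = slice_seq if strand == "+" else reverse_complement(slice_seq)
        ok = (
            not _contains_near_repeat(encode(spacer), locus.repeat_seq)
            and not _anchor_collision(spacer, locus)
            and _count_global_hits(spacer, enc_by_id) == 1
        )
        if not ok:
            arr[window[0] : window[1]] = saved
            continue
        occupied[rep.id].append(window)
        return spacer, TruthRecord(
            clone_id=clone_id,
            event_index=event_index,
            spacer_seq=spacer,
            source_replicon_id=rep.id,
            source_start=start,
            source_end=end,
            strand=strand,
            planted_mode=mode,
            slip_offset=slip_offset,
        )
    raise GenerationError(f"could not place an event with mode {mode!r}")


def _anchor_collision(spacer: str, locus: CRISPRLocus, max_mismatch: int = 2) -> bool:
    """Would this spacer be mistaken for the parental anchor spacer?"""
    first = locus.parental_spacers[0]
    if len(spacer) != len(first):
        return False
    return sum(a != b for a, b in zip(spacer, first)) <= max_mismatch


def _mutate(rng, seq: str, rate: float) -> str:
    """Per-base substitutions to a different base, probability ``rate``."""
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for i in hits:
        arr[i] = others[arr[i]][int(rng.integers(3))]
    return "".join(arr)


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    replicons: list[Replicon]
    locus: CRISPRLocus
    amplicons: list[tuple[str, str]]
    truth: list[TruthRecord]


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """End-to-end generation from a single seeded RNG stream."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    replicons = generate_replicons(config, rng)
    locus = generate_locus(config, rng)
    amplicons, truth, edited = plant_events(replicons, locus, config, rng)
    return SyntheticDataset(config, edited, locus, amplicons, truth)
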