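import numpy as np
import pytest

from spaceracq import (
    CRISPRLocus,
    GeneratorConfig,
    call_new_spacers,
    extract_spacers,
    find_repeats,
    generate_dataset,
    parse_amplicon,
)
from spaceracq.arrays import ArrayParseError, RearrangedError, UnanchoredError
from spaceracq.sequences import random_dna, reverse_complement
from spaceracq.synthetic import DEFAULT_REPEAT

R = DEFAULT_REPEAT
S1 = "ACGTTGCAGGTTACGATCCGTGCAATTGCAGGCTA"
S2 = "TTGACCATGGACGTTCAAGGTCCATAGCTAGGCTA"


class TestFindRepeats:
    def test_two_exact_repeats_at_known_offsets(self):
        amp = R + S1 + R
        assert find_repeats(amp, R, 0) == [(0, len(R)), (len(R) + len(S1), len(amp))]

    def test_one_substitution_found_only_with_tolerance(self):
        mutated = "C" + R[1:] if R[0] != "C" else "A" + R[1:]
        amp = R + S1 + mutated
        assert len(find_repeats(amp, R, 1)) == 2
        assert len(find_repeats(amp, R, 0)) == 1

    def test_repeat_longer_than_amplicon_yields_empty(self):
        assert find_repeats("ACGT", R, 0) == []

    def test_excessive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            find_repeats(R, R, len(R))

    def test_matches_brute_force_greedy_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            text = random_dna(rng, 2000, 0.38)
            # embed two exact copies and one 1-mismatch copy
            mutated = ("A" if R[5] != "A" else "C").join([R[:5], R[6:]])
            text = text[:100] + R + text[100:700] + mutated + text[700:1200] + R + text[1200:]
            got = find_repeats(text, R, 1)
            expected = _brute_greedy(text, R, 1)
            assert got == expected

    def test_greedy_consumes_span_in_overlap(self):
        # tandem AAAA... cannot yield overlapping matches
        text = "A" * 50
        intervals = find_repeats(text, "A" * 20, 0)
        starts = [s for s, _ in intervals]
        assert starts == [0, 20]


def _brute_greedy(text, repeat, max_mm):
    m = len(repeat)
    out = []
    i = 0
    while i + m <= len(text):
        if sum(a != b for a, b in zip(text[i : i + m], repeat)) <= max_mm:
            out.append((i, i + m))
            i += m
        else:
            i += 1
    return out


class TestExtractSpacers:
    def test_two_spacers_recovered_in_order(self):
        amp = R + S1 + R + S2 + R
        spacers, flagged = extract_spacers(amp, find_repeats(amp, R, 0))
        assert spacers == [S1, S2]
        assert flagged == []

    def test_zero_length_segment_flagged(self):
        amp = R + R + S1 + R
        spacers, flagged = extract_spacers(amp, find_repeats(amp, R, 0))
        assert spacers == [S1]
        assert len(flagged) == 1 and "short" in flagged[0][2]

    def test_oversized_segment_flagged(self):
        junk = "ACGT" * 30
        amp = R + junk + R
        spacers, flagged = extract_spacers(amp, find_repeats(amp, R, 0))
        assert spacers == []
        assert "long" in flagged[0][2]

    def test_fewer_than_two_repeats_is_unparseable(self):
        with pytest.raises(ArrayParseError):
            extract_spacers(R + S1, [(0, len(R))])


class TestCallNewSpacers:
    def test_parental_identity_gives_multiplicity_zero(self, toy_locus):
        new, mult = call_new_spacers(list(toy_locus.parental_spacers), toy_locus, 2)
        assert (new, mult) == ([], 0)

    def test_two_new_spacers(self, toy_locus):
        n1 = "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATT"
        n2 = "AAAACCCCGGGGTTTTAAAACCCCGGGGTTTTAA"
        new, mult = call_new_spacers(
            [n1, n2] + list(toy_locus.parental_spacers), toy_locus, 2
        )
        assert new == [n1, n2]
        assert mult == 2

    def test_truncated_parental_tail_is_accepted(self, toy_locus):
        spacers = list(toy_locus.parental_spacers[:2])
        assert call_new_spacers(spacers, toy_locus, 2) == ([], 0)

    def test_no_anchor_raises_unanchored(self, toy_locus):
        with pytest.raises(UnanchoredError):
            call_new_spacers(["TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATT"], toy_locus, 2)

    def test_wrong_parental_order_raises_rearranged(self, toy_locus):
        s = toy_locus.parental_spacers
        with pytest.raises(RearrangedError):
            call_new_spacers([s[0], s[2], s[1]], toy_locus, 2)


class TestParseAmplicon:
    def test_auto_orientation_recovers_reverse_complement(self, toy_locus):
        amp = toy_locus.parental_array
        parsed = parse_amplicon("c1", reverse_complement(amp), toy_locus)
        assert parsed.status == "ok"
        assert parsed.multiplicity == 0

    def test_trailing_primer_sequence_is_ignored(self, toy_locus):
        amp = toy_locus.parental_array + "GGGTTTACCCGGGTTT"
        parsed = parse_amplicon("c1", amp, toy_locus)
        assert parsed.status == "ok"
        assert [s.seq for s in parsed.spacers] == list(toy_locus.parental_spacers)

    def test_random_sequence_is_unparseable(self, toy_locus):
        rng = np.random.default_rng(5)
        parsed = parse_amplicon("c1", random_dna(rng, 500, 0.38), toy_locus)
        assert parsed.status == "unparseable"


class TestLocusInvariants:
    def test_short_repeat_rejected(self):
        with pytest.raises(ValueError):
            CRISPRLocus("A" * 20, "ACGT", ("ACGTACGTACGTACGTACGTACGTACGTAC",))

    def test_repeat_inside_spacer_rejected(self):
        with pytest.raises(ValueError):
            CRISPRLocus("A" * 20, R, (R + "ACGTACGTAC",))


def test_roundtrip_multiplicity_matches_truth_exactly():
    """Sum of clone multiplicities equals the planted event count, per clone."""
    cfg = GeneratorConfig(
        seed=202,
        n_clones=200,
        replicon_lengths={"host": 20000, "plasmid": 25000, "virus": 30000},
        multiplicity_weights={1: 0.6, 2: 0.25, 3: 0.14, 4: 0.01},
        source_weights={"plasmid": 0.5, "virus": 0.5},
    )
    ds = generate_dataset(cfg)
    truth_mult = {}
    for t in ds.truth:
        truth_mult[t.clone_id] = truth_mult.get(t.clone_id, 0) + 1
    for cid, seq in ds.amplicons:
        parsed = parse_amplicon(cid, seq, ds.locus)
        assert parsed.status == "ok"
        assert parsed.multiplicity == truth_mult.get(cid, 0)
        new = [s.seq for s in parsed.spacers if s.is_new]
        expected = [
            t.spacer_seq
            for t in sorted(
                (t for t in ds.truth if t.clone_id == cid),
                key=lambda t: t.event_index,
            )
        ]
        assert new == expected
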