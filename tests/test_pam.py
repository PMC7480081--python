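import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spaceracq import FlankPair, Replicon, classify_pam, extract_flanks
from spaceracq.mapping import ProtospacerHit
from spaceracq.pam import DEFAULT_SLIP_OFFSETS, PAM_CLASSES
from spaceracq.sequences import reverse_complement

flank6 = st.text(alphabet="ACGT", min_size=6, max_size=6)


def _hit(start, end, strand="+", rid="virus:v"):
    return ProtospacerHit("s", rid, rid.split(":")[0], start, end, strand, 0)


class TestExtractFlanks:
    def test_plus_strand_flanks(self):
        seq = "AAACCG" + "T" * 10 + "TGGAAA"
        rep = Replicon("virus:v", "virus", seq, circular=False)
        f = extract_flanks(_hit(6, 16), rep, 3, 3)
        assert (f.up, f.down, f.edge) == ("CCG", "TGG", False)

    def test_minus_strand_flanks_are_reverse_complemented(self):
        seq = "AAACCG" + "T" * 10 + "TGGAAA"
        rep = Replicon("virus:v", "virus", seq, circular=False)
        f = extract_flanks(_hit(6, 16, "-"), rep, 3, 3)
        # up in spacer orientation = rc of the plus-strand downstream 3-mer
        assert f.up == reverse_complement("TGG") == "CCA"
        assert f.down == reverse_complement("CCG") == "CGG"

    def test_linear_boundary_flags_edge(self):
        rep = Replicon("host:h", "host", "ACGT" * 10, circular=False)
        assert extract_flanks(_hit(2, 12), rep, 6, 6).edge
        assert extract_flanks(_hit(30, 38), rep, 6, 6).edge

    def test_circular_replicon_wraps(self):
        seq = "ACGTACGTACGTACGTACGT"
        rep = Replicon("plasmid:p", "plasmid", seq, circular=True)
        f = extract_flanks(_hit(2, 12), rep, 6, 6)
        assert not f.edge
        assert f.up == seq[-4:] + seq[:2]

    def test_edge_flanks_classify_as_other(self):
        assert classify_pam(FlankPair("", "", edge=True)).pam_class == "other"


class TestClassifyPam:
    @pytest.mark.parametrize(
        "up,down,expected,offset",
        [
            ("AAACCA", "AAAAAA", "canonical", None),  # 5'-CCN
            ("ATGATA", "TGGAAA", "flip", None),  # 3'-NGG
            ("CCTAAG", "TATATA", "slip", -3),  # CC shifted to -6,-5
            ("ACCTAG", "TATATA", "slip", -2),
            ("TACCTG", "TATATA", "slip", -1),
            ("TATACC", "TATATA", "slip", 1),  # CC at -2,-1
            ("TATATA", "TAGGAA", "slip", 1),  # GG at +3,+4
            ("TATATA", "TATGGA", "slip", 2),
            ("TATATA", "GGTATA", "slip", -1),  # GG at +1,+2
            ("AAACAG", "TATATA", "mismatch", None),  # CDN, D=A
            ("AAAGCG", "TATATA", "mismatch", None),  # DCN, D=G
            ("AAATAG", "TATATA", "other", None),
            ("NNNNCN", "TATATA", "other", None),  # N never matches C
        ],
    )
    def test_rule_table(self, up, down, expected, offset):
        call = classify_pam(FlankPair(up, down))
        assert call.pam_class == expected
        if expected == "slip":
            assert call.slip_offset == offset

    def test_priority_canonical_beats_flip(self):
        call = classify_pam(FlankPair("AAACCA", "TGGAAA"))
        assert call.pam_class == "canonical"

    def test_priority_flip_beats_slip(self):
        call = classify_pam(FlankPair("CCTAAG", "TGGAAA"))
        assert call.pam_class == "flip"

    @given(flank6, flank6)
    @settings(deadline=None, max_examples=300)
    def test_exhaustive_and_agrees_with_independent_rule_evaluator(self, up, down):
        call = classify_pam(FlankPair(up, down))
        assert call.pam_class in PAM_CLASSES
        assert call.pam_class == _reference_classifier(up, down)

    def test_canonical_flip_symmetry_on_random_placements(self, rng):
        """Storing the same protospacer inverted swaps canonical <-> flip."""
        for _ in range(50):
            up = "".join(rng.choice(list("ACGT"), size=6))
            up = up[:3] + "CC" + up[5:]  # force CC at -3,-2
            down = "".join(rng.choice(list("ACGT"), size=6))
            if down[1:3] == "GG":
                continue
            fwd = classify_pam(FlankPair(up, down))
            rev = classify_pam(
                FlankPair(reverse_complement(down), reverse_complement(up))
            )
            if fwd.pam_class == "canonical":
                assert rev.pam_class in ("canonical", "flip")
                if reverse_complement(down)[-3] != "C" or reverse_complement(down)[-2] != "C":
                    assert rev.pam_class == "flip"


def _reference_classifier(up, down):
    """Position-by-position re-statement of the five rules (test oracle)."""
    def up_at(pos):
        i = len(up) + pos
        return up[i] if 0 <= i < len(up) else None

    def down_at(pos):
        i = pos - 1
        return down[i] if 0 <= i < len(down) else None

    if up_at(-3) == "C" and up_at(-2) == "C":
        return "canonical"
    if down_at(2) == "G" and down_at(3) == "G":
        return "flip"
    for d in sorted((x for x in DEFAULT_SLIP_OFFSETS if x), key=lambda x: (abs(x), -x)):
        ups = [-3 + d, -2 + d]
        if all(-6 <= p <= -1 for p in ups) and all(up_at(p) == "C" for p in ups):
            return "slip"
        downs = [2 + d, 3 + d]
        if all(1 <= p <= 6 for p in downs) and all(down_at(p) == "G" for p in downs):
            return "slip"
    b3, b2 = up_at(-3), up_at(-2)
    if (b3 == "C" and b2 in "ATG") or (b3 in "ATG" and b2 == "C"):
        return "mismatch"
    return "other"


def test_planted_events_classify_to_their_planted_mode(small_dataset):
    """Generator flanks read back from the replicon classify as planted."""
    reps = {r.id: r for r in small_dataset.replicons}
    for t in small_dataset.truth:
        hit = ProtospacerHit(
            "s", t.source_replicon_id, t.source_replicon_id.split(":")[0],
            t.source_start, t.source_end, t.strand, 0,
        )
        flanks = extract_flanks(hit, reps[t.source_replicon_id])
        call = classify_pam(flanks)
        assert call.pam_class == t.planted_mode
        if t.planted_mode == "slip":
            assert call.slip_offset == t.slip_offset
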