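from functools import lru_cache

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dboxkit.conservation import (
    AlignmentResult,
    ScoringScheme,
    classify_column,
    column_classes,
    global_align,
    identity_table,
    map_conservation,
    percent_identity,
)
from dboxkit.sequences import AnnotatedSequence
from dboxkit.structure.model import Atom, Chain, Residue, StructureModel

SCHEME = ScoringScheme()
MATRIX = SCHEME.load_matrix()


def brute_force_score(a: str, b: str) -> float:
    """Optimal affine-gap global alignment score by exhaustive recursion
    over (position, position, gap-state) - independent of the aligner."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(MATRIX[a[i], b[j]] + rec(i + 1, j + 1, "m"))
        if i < len(a):  # gap in b
            cost = SCHEME.gap_extend if state == "gb" else SCHEME.gap_open
            options.append(-cost + rec(i + 1, j, "gb"))
        if j < len(b):  # gap in a
            cost = SCHEME.gap_extend if state == "ga" else SCHEME.gap_open
            options.append(-cost + rec(i, j + 1, "ga"))
        return max(options)

    return rec(0, 0, "m")


short_seq = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=8)


class TestGlobalAlign:
    def test_self_alignment_is_identity(self):
        s = AnnotatedSequence("s", "ACDEFG")
        aln = global_align(s, s)
        assert aln.alignedA == aln.alignedB == "ACDEFG"
        assert percent_identity(aln) == 100.0

    def test_single_gap_alignment_scored_correctly(self):
        a = AnnotatedSequence("a", "ACDEFG")
        b = AnnotatedSequence("b", "ACEFG")
        aln = global_align(a, b)
        assert aln.alignedA.replace("-", "") == "ACDEFG"
        assert aln.alignedB.replace("-", "") == "ACEFG"
        assert aln.score == brute_force_score("ACDEFG", "ACEFG")

    def test_dissimilar_sequences_zero_identity(self):
        aln = global_align(AnnotatedSequence("a", "AAAA"), AnnotatedSequence("b", "GGGG"))
        assert percent_identity(aln) == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_align(AnnotatedSequence("a", ""), AnnotatedSequence("b", "A"))

    @given(short_seq, short_seq)
    @settings(max_examples=40, deadline=None)
    def test_score_matches_brute_force_enumeration(self, a, b):
        aln = global_align(AnnotatedSequence("a", a), AnnotatedSequence("b", b))
        assert aln.score == pytest.approx(brute_force_score(a, b))

    def test_gap_removal_recovers_inputs(self):
        a = AnnotatedSequence("a", "MKVLINSDE")
        b = AnnotatedSequence("b", "MKINSQQDE")
        aln = global_align(a, b)
        assert aln.alignedA.replace("-", "") == a.residues
        assert aln.alignedB.replace("-", "") == b.residues


class TestPercentIdentity:
    def test_gap_and_mismatch_hand_count(self):
        # 5-column alignment, one gap column, X mismatching D: 3/4 gapless
        aln = AlignmentResult("x", "y", "ACD-E", "ACXDE", 0.0)
        assert percent_identity(aln) == pytest.approx(75.0)

    def test_alternative_denominators(self):
        aln = AlignmentResult("x", "y", "ACD-E", "ACXDE", 0.0)
        assert percent_identity(aln, "alignment") == pytest.approx(60.0)
        assert percent_identity(aln, "shorter") == pytest.approx(75.0)

    def test_symmetric(self):
        a = AnnotatedSequence("a", "MKVLINSDE")
        b = AnnotatedSequence("b", "MKINSQQDE")
        assert percent_identity(global_align(a, b)) == pytest.approx(
            percent_identity(global_align(b, a))
        )

    def test_all_gap_columns_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_identity(AlignmentResult("x", "y", "A-", "-C", 0.0))


class TestColumnClasses:
    @pytest.mark.parametrize(
        "column, expected",
        [("III", "identical"), ("IVL", "strong"), ("CSA", "weak"),
         ("DKG", "none"), ("AI-", "none"), ("FYW", "strong")],
    )
    def test_membership(self, column, expected):
        assert classify_column(column) == expected

    def test_identical_sequences_all_identical(self):
        ref = AnnotatedSequence("ref", "QPISVT")
        alns = [global_align(ref, AnnotatedSequence(f"s{i}", "QPISVT")) for i in range(3)]
        assert column_classes(ref, alns) == ["identical"] * 6

    def test_permutation_invariant(self):
        ref = AnnotatedSequence("ref", "QPISVTMVT")
        others = [AnnotatedSequence("a", "QPLSVTMIT"), AnnotatedSequence("b", "QPVSVTMLT")]
        alns = [global_align(ref, o) for o in others]
        assert column_classes(ref, alns) == column_classes(ref, alns[::-1])

    def test_wrong_reference_rejected(self):
        ref = AnnotatedSequence("ref", "QPISVT")
        other = global_align(AnnotatedSequence("x", "QQISVT"), ref)
        with pytest.raises(ValueError, match="anchored"):
            column_classes(ref, [other])


def _toy_chain_model(n=5, chain="E", start=1):
    residues = [
        Residue(start + i, "", "ALA", [Atom("CA", "C", [float(i), 0, 0])])
        for i in range(n)
    ]
    return StructureModel("toy", [Chain(chain, residues)])


class TestMapConservation:
    def test_full_coverage(self):
        model = _toy_chain_model(5)
        frame = map_conservation(["identical"] * 5, model, "E", numbering_offset=1)
        assert list(frame["class"]) == ["identical"] * 5

    def test_off_by_twelve_offset_flagged(self):
        # mimics the peptide's two author-numbering schemes (43- vs 55-based)
        model = _toy_chain_model(10, start=55)
        with pytest.raises(ValueError, match="systematically wrong"):
            map_conservation(["identical"] * 10, model, "E", numbering_offset=43)

    def test_single_residue(self):
        frame = map_conservation(["strong"], _toy_chain_model(1), "E", 1)
        assert len(frame) == 1 and frame["class"][0] == "strong"


def test_identity_table_matches_hand_counts():
    ref = AnnotatedSequence("ref", "QPISVTMVTPAD")
    others = [
        AnnotatedSequence("one_sub", "QPISVTMVTPAE"),   # 11/12
        AnnotatedSequence("two_subs", "QPLSVTMVSPAD"),  # 10/12
    ]
    table, _ = identity_table(ref, others)
    vals = dict(zip(table["seq_id"], table["percent_identity"]))
    assert vals["one_sub"] == pytest.approx(100 * 11 / 12, abs=0.01)
    assert vals["two_subs"] == pytest.approx(100 * 10 / 12, abs=0.01)
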