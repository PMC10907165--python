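import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dboxkit.motif import (
    CHOU_FASMAN_BETA,
    DBOX_PATTERN,
    beta_propensity_profile,
    classify_hydropathy,
    hydropathy_string,
    scan_dbox,
    score_motif,
)
from dboxkit.sequences import AnnotatedSequence, STANDARD_AA

seq_strategy = st.text(alphabet=sorted(STANDARD_AA), min_size=0, max_size=60)


@pytest.mark.parametrize(
    "residue, expected",
    [("I", "Φ"), ("V", "Φ"), ("M", "Φ"), ("S", "ζ"), ("T", "ζ"),
     ("Q", "ζ"), ("G", "ζ"), ("H", "ζ"), ("P", "P"), ("X", "ζ")],
)
def test_hydropathy_classes(residue, expected):
    assert classify_hydropathy(residue) == expected


def test_unknown_residue_rejected():
    with pytest.raises(ValueError, match="unknown residue"):
        classify_hydropathy("B")


@pytest.mark.parametrize(
    "seq, expected",
    [("ISVTMVT", DBOX_PATTERN), ("", ""), ("PPP", "PPP")],
)
def test_hydropathy_string_examples(seq, expected):
    assert hydropathy_string(seq) == expected


@given(seq_strategy)
@settings(max_examples=100, deadline=None)
def test_hydropathy_string_is_length_preserving(seq):
    assert len(hydropathy_string(seq)) == len(seq)


class TestPropensityProfile:
    def test_window_one_returns_table_values(self, dbox_peptide):
        prof = beta_propensity_profile(dbox_peptide, window=1)
        assert prof.scores == tuple(
            CHOU_FASMAN_BETA[aa] for aa in dbox_peptide.residues
        )
        assert not any(prof.truncated)

    def test_homopolymer_profile_is_constant(self):
        seq = AnnotatedSequence("v7", "VVVVVVV")
        prof = beta_propensity_profile(seq, window=5)
        assert all(s == pytest.approx(CHOU_FASMAN_BETA["V"]) for s in prof.scores)

    def test_strand_core_exceeds_threshold(self, dbox_peptide):
        # the S-V-T-M stretch (author 46-49) scores above the strand gate
        prof = beta_propensity_profile(dbox_peptide, window=5)
        for author in (46, 47, 48, 49):
            assert prof.scores[dbox_peptide.index_of(author)] > 1.0

    def test_oversized_window_flags_and_averages_whole_sequence(self):
        seq = AnnotatedSequence("s", "IVD")
        prof = beta_propensity_profile(seq, window=7)
        assert all(prof.truncated)
        whole = sum(CHOU_FASMAN_BETA[aa] for aa in "IVD") / 3
        assert prof.scores[1] == pytest.approx(whole)

    def test_even_window_rejected(self, dbox_peptide):
        with pytest.raises(ValueError, match="odd"):
            beta_propensity_profile(dbox_peptide, window=4)


class TestScanDbox:
    def test_printed_peptide_yields_single_flanked_match(self, dbox_peptide):
        matches = scan_dbox(dbox_peptide, proline_window=1)
        assert len(matches) == 1
        m = matches[0]
        assert (m.core_start, m.core_end) == (45, 51)
        assert m.core_sequence == "ISVTMVT"
        assert (m.upstream_proline, m.downstream_proline) == (44, 52)
        assert m.passes_propensity

    def test_homopolymer_has_no_matches(self):
        assert scan_dbox(AnnotatedSequence("a", "AAAAAAAAAA")) == []

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            scan_dbox(AnnotatedSequence("s", "IVTIV"))

    def test_matches_ascending_and_overlaps_reported(self):
        # two overlapping pattern hits, no proline requirement
        seq = AnnotatedSequence("ov", "ISISVVSVSVVT")  # hits at cores 1 and 6
        hits = scan_dbox(seq, require_prolines=False, propensity_threshold=None)
        starts = [m.core_start for m in hits]
        assert starts == sorted(starts)
        assert starts == [1, 6]

    @given(seq_strategy.filter(lambda s: len(s) >= 7))
    @settings(max_examples=100, deadline=None)
    def test_every_match_rederives_the_pattern(self, seq):
        aseq = AnnotatedSequence("rand", seq)
        for m in scan_dbox(aseq, require_prolines=False, propensity_threshold=None):
            i = aseq.index_of(m.core_start)
            assert hydropathy_string(seq[i : i + 7]) == DBOX_PATTERN


class TestScoreMotif:
    def _match(self, dbox_peptide, prop):
        m = scan_dbox(dbox_peptide, proline_window=1)[0]
        return type(m)(**{**m.__dict__, "mean_core_propensity": prop})

    def test_monotone_in_propensity(self, dbox_peptide):
        prof = beta_propensity_profile(dbox_peptide)
        hi = score_motif(self._match(dbox_peptide, 1.2), prof)
        lo = score_motif(self._match(dbox_peptide, 1.0), prof)
        assert hi > lo

    def test_reduces_to_propensity_without_anchor(self, dbox_peptide):
        prof = beta_propensity_profile(dbox_peptide)
        m = scan_dbox(dbox_peptide, proline_window=1)[0]
        assert score_motif(m, prof) == pytest.approx(m.mean_core_propensity)

    def test_anchor_distance_penalty(self, dbox_peptide):
        prof = beta_propensity_profile(dbox_peptide)
        m = scan_dbox(dbox_peptide, proline_window=1)[0]
        near = score_motif(m, prof, anchor_end=m.core_start)
        far = score_motif(m, prof, anchor_end=m.core_start - 50)
        assert near > far

    def test_mismatched_profile_rejected(self, dbox_peptide):
        other = beta_propensity_profile(AnnotatedSequence("other", "IVTIVTT"))
        m = scan_dbox(dbox_peptide, proline_window=1)[0]
        with pytest.raises(ValueError, match="profile"):
            score_motif(m, other)
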