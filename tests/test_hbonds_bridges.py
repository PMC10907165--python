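import numpy as np
import pytest

from dboxkit.structure import (
    classify_bridges,
    detect_backbone_hbonds,
    detect_strand_recruitment,
    sheet_topology,
)
from dboxkit.structure.hbonds import backbone_units, kabsch_sander_energy
from dboxkit.structure.model import StructureModel
from dboxkit.synthetic import (
    build_backbone,
    expected_bridge_pairs,
    gen_ideal_beta_pair,
    gen_ideal_helix,
    gen_recruitment_fixture,
    STRAND_PHI_PSI,
    _add_amide_hydrogens,
    _to_chain,
)


def inter_chain(bonds):
    return [b for b in bonds if b.donor.chain_id != b.acceptor.chain_id]


def bond_keys(bonds):
    return {
        ((b.donor.chain_id, b.donor.number),
         (b.acceptor.chain_id, b.acceptor.number))
        for b in bonds
    }


def test_single_extended_strand_has_no_bonds():
    residues = build_backbone(8, *STRAND_PHI_PSI["antiparallel"])
    _add_amide_hydrogens(residues)
    model = StructureModel("strand", [_to_chain(residues, "A")])
    assert detect_backbone_hbonds(model) == []


def test_helix_has_n_to_n4_bonds_only():
    model = gen_ideal_helix(12)
    bonds = detect_backbone_hbonds(model)
    assert bonds, "ideal helix must show the 4-turn ladder"
    assert {b.donor.number - b.acceptor.number for b in bonds} == {4}


@pytest.mark.parametrize("kind", ["parallel", "antiparallel"])
@pytest.mark.parametrize("n_res", range(3, 11))
def test_ideal_pair_bond_ladder_and_bridge_types(kind, n_res):
    """The fixture's analytically enumerated ladder is detected exactly and
    every bridge carries the constructed type, for lengths 3-10."""
    model, expected = gen_ideal_beta_pair(kind, n_res)
    bonds = detect_backbone_hbonds(model)
    assert bond_keys(inter_chain(bonds)) == set(expected)
    bridges = [
        b for b in classify_bridges(bonds, model) if b.res_i[0] != b.res_j[0]
    ]
    assert bridges
    assert {b.type for b in bridges} == {kind}
    got = sorted(
        (b.res_i[1], b.res_j[1]) if b.res_i[0] == "A" else (b.res_j[1], b.res_i[1])
        for b in bridges
    )
    assert got == sorted(expected_bridge_pairs(kind, n_res))


def test_separated_strands_have_no_bonds():
    model, _ = gen_ideal_beta_pair("antiparallel", 5, separation=20.0)
    assert inter_chain(detect_backbone_hbonds(model)) == []


def test_kabsch_sander_energy_of_textbook_geometry():
    # linear N-H...O=C at 2.9 A N...O is comfortably below the -0.5 cutoff
    model, _ = gen_ideal_beta_pair("antiparallel", 5)
    units = {(u.chain_id, u.number): u for u in backbone_units(model)}
    E = kabsch_sander_energy(units[("A", 1)], units[("B", 5)])
    assert E is not None and E < -1.0


def test_geometric_criterion_finds_the_same_ladder():
    model, expected = gen_ideal_beta_pair("antiparallel", 6)
    geo = detect_backbone_hbonds(model, criterion="geometric")
    assert bond_keys(inter_chain(geo)) == set(expected)


class TestTopology:
    def test_two_strand_fixture(self):
        model, _ = gen_ideal_beta_pair("antiparallel", 6)
        per_chain = [sheet_topology(model, cid) for cid in model.chain_ids()]
        assert sum(t.n_strands for t in per_chain) == 2
        assert sum(t.n_helices for t in per_chain) == 0

    def test_ideal_helix(self):
        topo = sheet_topology(gen_ideal_helix(12), "A")
        assert (topo.n_strands, topo.n_helices) == (0, 1)

    def test_short_chain_rejected(self):
        model = gen_ideal_helix(8)
        model.chain("A").residues = model.chain("A").residues[:3]
        with pytest.raises(ValueError, match="residues"):
            sheet_topology(model, "A")


class TestRecruitment:
    @pytest.fixture(scope="class")
    @staticmethod
    def fixture():
        return gen_recruitment_fixture(7)

    def test_two_sheet_recruitment_detected(self, fixture):
        model, _ = fixture
        report = detect_strand_recruitment(model, "P")
        assert report.recruited_to_two_sheets
        assert report.partner_chains == ("A", "B")
        types = {
            (l.chain_i if l.chain_i != "P" else l.chain_j): l.type
            for l in report.ladders
        }
        assert types == {"A": "parallel", "B": "antiparallel"}

    def test_single_ladder_pair_is_one_partner_flag_off(self):
        model, _ = gen_ideal_beta_pair("parallel", 6)
        report = detect_strand_recruitment(model, "A")
        assert not report.recruited_to_two_sheets
        assert report.partner_chains == ("B",)

    def test_peptide_without_bridges_gives_empty_report(self):
        model, _ = gen_ideal_beta_pair("antiparallel", 5, separation=20.0)
        report = detect_strand_recruitment(model, "A")
        assert report.ladders == []
        assert not report.recruited_to_two_sheets

    def test_missing_peptide_chain_names_available(self, fixture):
        model, _ = fixture
        with pytest.raises(KeyError, match="available"):
            detect_strand_recruitment(model, "Z")

    def test_report_serializes(self, fixture):
        model, _ = fixture
        d = detect_strand_recruitment(model, "P").to_dict()
        assert d["recruited_to_two_sheets"] is True
        assert {l["type"] for l in d["ladders"]} == {"parallel", "antiparallel"}
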