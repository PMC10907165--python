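"""Beta-bridge classification, sheet/helix topology, strand recruitment.

Bridge typing follows the Kabsch-Sander rules, in their original
acceptor-first notation Hbond(x, y) = "the C=O of residue x accepts a bond
from the N-H of residue y". A residue pair (i, j) forms a

  parallel bridge      iff  {Hbond(i-1, j) and Hbond(j, i+1)}
                        or  {Hbond(j-1, i) and Hbond(i, j+1)}
  antiparallel bridge  iff  {Hbond(i, j) and Hbond(j, i)}
                        or  {Hbond(i-1, j+1) and Hbond(j-1, i+1)}

(the parallel first clause, read in donor terms, is "j donates to i-1 and
i+1 donates to j" - the familiar slanted bonds of a parallel sheet).

"Strand recruitment" - the binding mode in which a free peptide joins the
edge of a pre-existing sheet, as the TonB D-box does on the ExbD dimer -
is detected as one or more bridge ladders between a designated peptide
chain and partner chains, combined with burial of the peptide's
hydrophobic side chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from ..motif import DEFAULT_PHI_SET, classify_hydropathy
from .hbonds import HBond, backbone_units, detect_backbone_hbonds
from .model import StructureModel
from .sasa import fractional_burial

BridgeType = Literal["parallel", "antiparallel"]
ResKey = tuple[str, int, str]  # chain, author number, icode


@dataclass(frozen=True)
class BetaBridge:
    res_i: ResKey
    res_j: ResKey
    type: BridgeType


@dataclass(frozen=True)
class BridgeLadder:
    """Maximal run of same-type bridges between one pair of chains."""

    chain_i: str
    chain_j: str
    type: BridgeType
    bridges: tuple[BetaBridge, ...]

    @property
    def range_i(self) -> tuple[int, int]:
        nums = [b.res_i[1] for b in self.bridges]
        return min(nums), max(nums)

    @property
    def range_j(self) -> tuple[int, int]:
        nums = [b.res_j[1] for b in self.bridges]
        return min(nums), max(nums)


def classify_bridges(hbonds: list[HBond], model: StructureModel) -> list[BetaBridge]:
    """Apply the Kabsch-Sander bridge rules to a detected H-bond list.

    Neighbour indices (i-1, i+1) refer to chain-sequential positions; pairs
    closer than 3 in sequence on the same chain are not bridges.
    """
    units = backbone_units(model)
    by_index = {u.index: u for u in units}
    # K-S acceptor-first pairs: (x, y) means CO(x) accepts from NH(y)
    bond_set = {(b.acceptor.index, b.donor.index) for b in hbonds}

    def hb(x: int | None, y: int | None) -> bool:
        return x is not None and y is not None and (x, y) in bond_set

    def nbr(idx: int, step: int) -> int | None:
        u = by_index.get(idx)
        v = by_index.get(idx + step)
        if u is None or v is None or v.chain_id != u.chain_id:
            return None
        if v.chain_pos != u.chain_pos + step:
            return None
        return v.index

    candidates = set()
    for x, y in bond_set:
        for i, j in ((x, y), (y, x)):
            candidates.update(
                (i + di, j + dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
            )
    bridges: list[BetaBridge] = []
    seen = set()
    for i, j in sorted(candidates):
        u, v = by_index.get(i), by_index.get(j)
        if u is None or v is None:
            continue
        if u.chain_id == v.chain_id and (
            i >= j or abs(u.chain_pos - v.chain_pos) < 3
        ):
            continue  # count same-chain pairs once (i < j), skip near pairs
        if (j, i) in seen:
            continue
        im1, ip1 = nbr(i, -1), nbr(i, +1)
        jm1, jp1 = nbr(j, -1), nbr(j, +1)
        par = (hb(im1, j) and hb(j, ip1)) or (hb(jm1, i) and hb(i, jp1))
        anti = (hb(i, j) and hb(j, i)) or (hb(im1, jp1) and hb(jm1, ip1))
        btype: BridgeType | None = (
            "parallel" if par else "antiparallel" if anti else None
        )
        if btype is None:
            continue
        seen.add((i, j))
        bridges.append(BetaBridge(u.key, v.key, btype))
    return bridges


def assemble_ladders(bridges: list[BetaBridge], max_gap: int = 2) -> list[BridgeLadder]:
    """Group bridges into ladders: same chain pair, same type, positions
    within ``max_gap`` residues of the previous bridge on both strands."""
    groups: dict[tuple[str, str, str], list[BetaBridge]] = {}
    for b in bridges:
        ci, cj = b.res_i[0], b.res_j[0]
        key = (ci, cj, b.type) if ci <= cj else (cj, ci, b.type)
        bb = b if ci <= cj else BetaBridge(b.res_j, b.res_i, b.type)
        groups.setdefault(key, []).append(bb)
    ladders: list[BridgeLadder] = []
    for (ci, cj, btype), items in sorted(groups.items()):
        items.sort(key=lambda b: (b.res_i[1], b.res_j[1]))
        run: list[BetaBridge] = []
        for b in items:
            if run and (
                abs(b.res_i[1] - run[-1].res_i[1]) > max_gap
                or abs(b.res_j[1] - run[-1].res_j[1]) > max_gap
            ):
                ladders.append(BridgeLadder(ci, cj, btype, tuple(run)))
                run = []
            run.append(b)
        if run:
            ladders.append(BridgeLadder(ci, cj, btype, tuple(run)))
    return ladders


@dataclass(frozen=True)
class ChainTopology:
    chain_id: str
    n_strands: int
    n_helices: int
    strand_ranges: tuple[tuple[int, int], ...]
    helix_ranges: tuple[tuple[int, int], ...]


def sheet_topology(model: StructureModel, chain_id: str,
                   hbonds: list[HBond] | None = None) -> ChainTopology:
    """Strand and helix counts of one protein chain.

    Strands are maximal runs (length >= 2, single-residue gaps filled) of
    residues participating in any beta bridge; helices are maximal runs
    (length >= 4) of residues i whose C=O accepts an n+4 -> n backbone bond,
    the Kabsch-Sander 4-turn pattern.
    """
    chain = model.chain(chain_id)
    nres = len(chain.protein_residues())
    if nres < 5:
        raise ValueError(f"chain {chain_id!r} has only {nres} residues")
    if hbonds is None:
        hbonds = detect_backbone_hbonds(model)
    bridges = classify_bridges(hbonds, model)
    units = [u for u in backbone_units(model) if u.chain_id == chain_id]
    pos_by_key = {u.key: u.chain_pos for u in units}
    numbers = {u.chain_pos: u.number for u in units}

    in_bridge = set()
    for b in bridges:
        for key in (b.res_i, b.res_j):
            if key in pos_by_key:
                in_bridge.add(pos_by_key[key])
    # fill single gaps so that alternating bridge registers form one strand
    filled = set(in_bridge)
    for p in list(in_bridge):
        if p + 2 in in_bridge:
            filled.add(p + 1)
    strand_ranges = [r for r in _runs(filled) if r[1] - r[0] + 1 >= 2]

    turn_accept = set()
    for hb in hbonds:
        if hb.donor.chain_id == chain_id and hb.acceptor.chain_id == chain_id:
            if hb.donor.chain_pos - hb.acceptor.chain_pos == 4:
                turn_accept.add(hb.acceptor.chain_pos)
    helix_ranges = [r for r in _runs(turn_accept) if r[1] - r[0] + 1 >= 4]

    def to_author(ranges):
        return tuple((numbers[a], numbers[b]) for a, b in ranges)

    return ChainTopology(
        chain_id=chain_id,
        n_strands=len(strand_ranges),
        n_helices=len(helix_ranges),
        strand_ranges=to_author(strand_ranges),
        helix_ranges=to_author(helix_ranges),
    )


def _runs(positions: set[int]) -> list[tuple[int, int]]:
    runs = []
    for p in sorted(positions):
        if runs and p == runs[-1][1] + 1:
            runs[-1][1] = p
        else:
            runs.append([p, p])
    return [tuple(r) for r in runs]


@dataclass
class RecruitmentReport:
    """Per-interface summary of beta-strand recruitment of a peptide chain."""

    peptide_chain: str
    ladders: list[BridgeLadder]
    burial: dict[int, float | None]       # peptide phi-position side chains
    recruited_to_two_sheets: bool
    partner_chains: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "peptide_chain": self.peptide_chain,
            "partner_chains": list(self.partner_chains),
            "recruited_to_two_sheets": self.recruited_to_two_sheets,
            "ladders": [
                {
                    "partner_chain": (
                        l.chain_j if l.chain_i == self.peptide_chain else l.chain_i
                    ),
                    "type": l.type,
                    "peptide_range": list(
                        l.range_i if l.chain_i == self.peptide_chain else l.range_j
                    ),
                    "partner_range": list(
                        l.range_j if l.chain_i == self.peptide_chain else l.range_i
                    ),
                    "n_bridges": len(l.bridges),
                }
                for l in self.ladders
            ],
            "phi_sidechain_burial": {
                str(k): v for k, v in self.burial.items()
            },
        }


def detect_strand_recruitment(model: StructureModel, peptide_chain: str,
                              hbonds: list[HBond] | None = None,
                              sasa_points: int = 240) -> RecruitmentReport:
    """Detect recruitment of ``peptide_chain`` to partner beta sheets.

    Reports every bridge ladder between the peptide and each partner chain
    (type and author-numbered residue ranges) plus fractional side-chain
    burial of the peptide's hydrophobic (phi-class) residues against all
    partner chains. The two-sheet recruitment flag is set iff ladders to at
    least two distinct partner chains exist.
    """
    chain = model.chain(peptide_chain)  # raises KeyError with available ids
    if len(model.chains) < 2:
        raise ValueError("model must contain the peptide plus at least one partner chain")
    if hbonds is None:
        hbonds = detect_backbone_hbonds(model)
    inter = [
        hb for hb in hbonds
        if (hb.donor.chain_id == peptide_chain) != (hb.acceptor.chain_id == peptide_chain)
    ]
    bridges = classify_bridges(hbonds, model)
    pep_bridges = [
        b for b in bridges
        if (b.res_i[0] == peptide_chain) != (b.res_j[0] == peptide_chain)
    ]
    ladders = assemble_ladders(pep_bridges)
    partners = tuple(sorted({
        l.chain_j if l.chain_i == peptide_chain else l.chain_i for l in ladders
    }))
    phi_residues = [
        r.number for r in chain.protein_residues()
        if r.one_letter != "X"
        and classify_hydropathy(r.one_letter) == classify_hydropathy("V")
        and r.sidechain_atoms()
    ]
    burial: dict[int, float | None] = {}
    if phi_residues and len(model.chains) > 1:
        burial = fractional_burial(
            model, peptide_chain, target_residues=phi_residues,
            n_points=sasa_points,
        )
    return RecruitmentReport(
        peptide_chain=peptide_chain,
        ladders=ladders,
        burial=burial,
        recruited_to_two_sheets=len(partners) >= 2,
        partner_chains=partners,
    )
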