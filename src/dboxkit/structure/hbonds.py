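"""Backbone hydrogen-bond detection (Kabsch-Sander energy or geometry).

The Kabsch-Sander model places partial charges on the backbone C=O and N-H
groups and scores a putative bond by the electrostatic energy

    E = q1*q2*f * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with q1*q2*f = 27.888 kcal*Angstrom/mol; a bond is assigned when
E < -0.5 kcal/mol. When the amide hydrogen is absent from the model it is
built at 1.0 Angstrom from N along the direction of the previous residue's
C=O bond (the standard in-plane placement); the first residue of a chain,
residues following a chain break, and proline cannot donate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model import Residue, StructureModel

KS_COUPLING = 27.888       # q1*q2*f, kcal*Angstrom/mol
KS_CUTOFF = -0.5           # kcal/mol
PEPTIDE_BOND_MAX = 2.5     # Angstrom, C(i-1)-N(i) above this is a chain break
MIN_DIST = 0.5             # clash guard for the 1/r terms


@dataclass(frozen=True)
class BackboneUnit:
    """One residue's backbone as seen by the H-bond detector."""

    chain_id: str
    number: int
    icode: str
    name: str
    index: int                 # global sequential index across the model
    chain_pos: int             # position within its chain
    N: np.ndarray | None
    CA: np.ndarray | None
    C: np.ndarray | None
    O: np.ndarray | None
    H: np.ndarray | None       # None => cannot donate

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)


@dataclass(frozen=True)
class HBond:
    donor: BackboneUnit        # provides N-H
    acceptor: BackboneUnit     # provides C=O
    energy: float              # kcal/mol (Kabsch-Sander) or geometric score
    distance: float            # N...O, Angstrom


def backbone_units(model: StructureModel) -> list[BackboneUnit]:
    """Extract backbone geometry, building amide hydrogens where absent."""
    units: list[BackboneUnit] = []
    index = 0
    for chain in model.chains:
        prev: Residue | None = None
        for pos, res in enumerate(chain.protein_residues()):
            N = res.atom("N")
            CA = res.atom("CA")
            C = res.atom("C")
            O = res.atom("O")
            get = lambda a: None if a is None else a.pos
            H_atom = res.atom("H") or res.atom("HN")
            H = None if H_atom is None else H_atom.pos
            if H is None and N is not None and res.name != "PRO" and prev is not None:
                pC, pO = prev.atom("C"), prev.atom("O")
                if (
                    pC is not None and pO is not None
                    and np.linalg.norm(pC.pos - N.pos) <= PEPTIDE_BOND_MAX
                ):
                    v = pC.pos - pO.pos
                    nv = np.linalg.norm(v)
                    if nv > 0:
                        H = N.pos + v / nv
            units.append(
                BackboneUnit(
                    chain_id=chain.id, number=res.number, icode=res.icode,
                    name=res.name, index=index, chain_pos=pos,
                    N=get(N), CA=get(CA), C=get(C), O=get(O), H=H,
                )
            )
            prev = res
            index += 1
    return units


def kabsch_sander_energy(donor: BackboneUnit, acceptor: BackboneUnit) -> float | None:
    """K-S electrostatic energy of donor N-H with acceptor C=O, or None if
    the needed atoms are missing or clashing."""
    if donor.N is None or donor.H is None or acceptor.C is None or acceptor.O is None:
        return None
    rON = np.linalg.norm(acceptor.O - donor.N)
    rCH = np.linalg.norm(acceptor.C - donor.H)
    rOH = np.linalg.norm(acceptor.O - donor.H)
    rCN = np.linalg.norm(acceptor.C - donor.N)
    if min(rON, rCH, rOH, rCN) < MIN_DIST:
        return None
    return KS_COUPLING * (1.0 / rON + 1.0 / rCH - 1.0 / rOH - 1.0 / rCN)


def _geometric_ok(donor: BackboneUnit, acceptor: BackboneUnit,
                  max_HO: float = 2.5, max_NO: float = 3.5,
                  min_angle: float = 120.0) -> tuple[bool, float]:
    if donor.N is None or donor.H is None or acceptor.O is None:
        return False, np.inf
    rNO = float(np.linalg.norm(acceptor.O - donor.N))
    rHO = float(np.linalg.norm(acceptor.O - donor.H))
    if rHO > max_HO or rNO > max_NO:
        return False, rNO
    v1 = donor.N - donor.H
    v2 = acceptor.O - donor.H
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angle > min_angle, rNO


def detect_backbone_hbonds(model: StructureModel,
                           criterion: Literal["kabsch_sander", "geometric"] = "kabsch_sander",
                           cutoff: float = KS_CUTOFF,
                           max_ca_distance: float = 9.0) -> list[HBond]:
    """All backbone N-H -> C=O hydrogen bonds in the model.

    Pairs within the same chain at sequence separation <= 1 are excluded;
    candidate pairs are pre-screened by Ca-Ca distance. Each (donor,
    acceptor) pair is reported once.
    """
    units = backbone_units(model)
    cas = np.array([
        u.CA if u.CA is not None else np.full(3, np.nan) for u in units
    ])
    bonds: list[HBond] = []
    for d in units:
        if d.H is None:
            continue
        for a in units:
            if a.O is None or a.index == d.index:
                continue
            if d.chain_id == a.chain_id and abs(d.chain_pos - a.chain_pos) <= 1:
                continue
            ca_d, ca_a = cas[d.index], cas[a.index]
            if np.all(np.isfinite(ca_d)) and np.all(np.isfinite(ca_a)):
                if np.linalg.norm(ca_d - ca_a) > max_ca_distance:
                    continue
            if criterion == "kabsch_sander":
                E = kabsch_sander_energy(d, a)
                if E is not None and E < cutoff:
                    bonds.append(
                        HBond(d, a, E, float(np.linalg.norm(a.O - d.N)))
                    )
            elif criterion == "geometric":
                ok, rNO = _geometric_ok(d, a)
                if ok:
                    bonds.append(HBond(d, a, -rNO, rNO))
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
    return bonds
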