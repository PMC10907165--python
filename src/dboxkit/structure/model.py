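"""Structure container and PDB/mmCIF input-output (via gemmi).

`StructureModel` is a deliberately small, analysis-oriented container:
ordered chains of ordered residues of atoms with numpy coordinates. It is
the substrate for superposition, SASA, hydrogen-bond and bridge analyses;
crystallographic bookkeeping (symmetry, anisotropic B, etc.) stays in
gemmi and is not carried along.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import gemmi
import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O"}
WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")


@dataclass
class Residue:
    number: int          # author residue number
    icode: str           # insertion code ('' if none)
    name: str            # 3-letter residue name
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def sidechain_atoms(self, include_hydrogens: bool = False) -> list[Atom]:
        """Non-backbone atoms; heavy atoms only unless requested.
        CB counts as side chain; glycine therefore has none."""
        return [
            a for a in self.atoms
            if a.name not in BACKBONE_ATOMS
            and (include_hydrogens or a.element != "H")
        ]

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_water]

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.protein_residues())

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None


@dataclass
class StructureModel:
    name: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in {self.name!r}: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(
            f"chain {chain_id!r} not in model {self.name!r}; "
            f"available: {[c.id for c in self.chains]}"
        )

    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def iter_atoms(self, include_waters: bool = False,
                   include_hydrogens: bool = True
                   ) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                if r.is_water and not include_waters:
                    continue
                for a in r.atoms:
                    if a.element == "H" and not include_hydrogens:
                        continue
                    yield c, r, a

    def subset(self, chain_ids: list[str]) -> "StructureModel":
        """New model containing only the named chains (shared atoms)."""
        return StructureModel(
            self.name, [c for c in self.chains if c.id in chain_ids]
        )


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one location per atom name: highest occupancy, ties broken by
    altloc label order."""
    best: dict[str, Atom] = {}
    for a in atoms:
        cur = best.get(a.name)
        if cur is None or a.occupancy > cur.occupancy or (
            a.occupancy == cur.occupancy and a.altloc < cur.altloc
        ):
            best[a.name] = a
    # preserve first-seen order of atom names
    seen, out = set(), []
    for a in atoms:
        if a.name not in seen:
            seen.add(a.name)
            out.append(best[a.name])
    return out


def read_structure(path: str | Path,
                   format: Literal["auto", "pdb", "mmcif"] = "auto",
                   model_index: int = 0) -> StructureModel:
    """Read a PDB or mmCIF file into a `StructureModel`.

    The requested model (first by default) is taken; alternate locations
    are collapsed to the highest-occupancy copy; waters and hydrogens are
    retained (analyses exclude them themselves).
    """
    path = Path(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: file contains no models")
    if model_index >= len(st):
        raise ValueError(f"{path}: model index {model_index} out of range ({len(st)} models)")
    gmodel = st[model_index]
    chains = []
    for gchain in gmodel:
        residues = []
        for gres in gchain:
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name.upper(),
                    pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    altloc=ga.altloc or "",
                )
                for ga in gres
            ]
            residues.append(
                Residue(
                    number=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    name=gres.name,
                    atoms=_resolve_altlocs(atoms),
                )
            )
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains or all(not c.residues for c in chains):
        raise ValueError(f"{path}: model {model_index} is empty")
    return StructureModel(path.stem, chains)


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.name
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = atom.occupancy
                ga.altloc = atom.altloc or "\0"
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    return st


def write_pdb(model: StructureModel, path: str | Path) -> None:
    st = to_gemmi(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_mmcif(model: StructureModel, path: str | Path) -> None:
    st = to_gemmi(model)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))
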