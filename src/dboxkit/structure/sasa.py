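"""Shrake-Rupley solvent-accessible surface area and fractional burial.

Each atom is inflated by the probe radius and sampled with a deterministic
quasi-uniform (Fibonacci-lattice) point set; a sample point is accessible
iff it lies outside every neighbouring atom's inflated sphere. Per-atom
area is the accessible fraction of the inflated sphere's area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .model import Residue, StructureModel

#: United-atom-style van der Waals radii (Angstrom) for heavy atoms.
DEFAULT_RADII: Mapping[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "H": 1.20, "D": 1.20,
}

AtomKey = tuple[str, int, str, str]  # chain, residue number, icode, atom name
ResidueKey = tuple[str, int, str]


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SASAResult:
    per_atom: dict[AtomKey, float]          # Angstrom^2
    per_residue: dict[ResidueKey, float]    # all-atom totals
    per_residue_sidechain: dict[ResidueKey, float]
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(sum(self.per_atom.values()))


def compute_sasa(model: StructureModel, probe: float = 1.4, n_points: int = 960,
                 radii: Mapping[str, float] = DEFAULT_RADII,
                 include_waters: bool = False,
                 include_hydrogens: bool = False) -> SASAResult:
    """Shrake-Rupley SASA of every (heavy, non-water) atom in the model."""
    atoms: list[tuple[AtomKey, ResidueKey, bool, np.ndarray, float]] = []
    for chain, res, atom in model.iter_atoms(include_waters=include_waters,
                                             include_hydrogens=include_hydrogens):
        if atom.element not in radii:
            raise ValueError(
                f"no radius for element {atom.element!r} "
                f"(atom {atom.name} in {chain.id}/{res.name}{res.number}{res.icode})"
            )
        akey = (chain.id, res.number, res.icode, atom.name)
        rkey = (chain.id, res.number, res.icode)
        is_side = atom.name not in {"N", "CA", "C", "O"}
        atoms.append((akey, rkey, is_side, atom.pos, radii[atom.element] + probe))
    if not atoms:
        raise ValueError("no atoms to compute SASA over")
    coords = np.array([a[3] for a in atoms])
    rads = np.array([a[4] for a in atoms])
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = rads.max()
    per_atom: dict[AtomKey, float] = {}
    per_res: dict[ResidueKey, float] = {}
    per_res_sc: dict[ResidueKey, float] = {}
    for i, (akey, rkey, is_side, pos, ri) in enumerate(atoms):
        pts = pos + ri * sphere
        nbrs = [j for j in tree.query_ball_point(pos, ri + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d > rads[j]
            if not accessible.any():
                break
        area = 4.0 * np.pi * ri * ri * accessible.sum() / n_points
        per_atom[akey] = area
        per_res[rkey] = per_res.get(rkey, 0.0) + area
        if is_side:
            per_res_sc[rkey] = per_res_sc.get(rkey, 0.0) + area
    return SASAResult(per_atom, per_res, per_res_sc, probe, n_points)


def fractional_burial(model: StructureModel, target_chain: str,
                      target_residues: list[int] | None = None,
                      partner_chains: list[str] | None = None,
                      probe: float = 1.4, n_points: int = 960,
                      radii: Mapping[str, float] = DEFAULT_RADII,
                      ) -> dict[int, float | None]:
    """Fractional side-chain burial of target residues upon complexation.

    burial = 1 - (side-chain SASA in the complex) /
                 (side-chain SASA of the target chain in isolation),
    clamped to [0, 1]. The isolated reference is the whole target chain
    with every partner chain removed. Glycine (no side-chain heavy atoms)
    is reported as None.
    """
    chain = model.chain(target_chain)
    if partner_chains is None:
        partner_chains = [c for c in model.chain_ids() if c != target_chain]
    if target_chain in partner_chains:
        raise ValueError("target and partner selections must be disjoint")
    if not partner_chains:
        raise ValueError("partner selection is empty")
    residues = [
        r for r in chain.protein_residues()
        if target_residues is None or r.number in target_residues
    ]
    if not residues:
        raise ValueError(f"no target residues selected in chain {target_chain!r}")
    iso = compute_sasa(model.subset([target_chain]), probe, n_points, radii)
    cpx = compute_sasa(model.subset([target_chain] + partner_chains),
                       probe, n_points, radii)
    out: dict[int, float | None] = {}
    for r in residues:
        key = (target_chain, r.number, r.icode)
        iso_sc = iso.per_residue_sidechain.get(key, 0.0)
        if not r.sidechain_atoms() or iso_sc <= 0.0:
            out[r.number] = None  # glycine or fully pre-buried side chain
            continue
        cpx_sc = cpx.per_residue_sidechain.get(key, 0.0)
        out[r.number] = float(np.clip(1.0 - cpx_sc / iso_sc, 0.0, 1.0))
    return out


def two_sphere_cap_area(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Closed-form accessible areas of two intersecting spheres (test oracle).

    Returns the exposed areas of spheres with radii ``r1`` and ``r2`` whose
    centres are ``d`` apart; each loses a spherical cap of area
    ``2*pi*r*h`` where ``h`` is the cap height at the intersection plane.
    """
    if d >= r1 + r2:
        return 4 * np.pi * r1 ** 2, 4 * np.pi * r2 ** 2
    if d <= abs(r1 - r2):
        small, big = sorted((r1, r2))
        return (0.0, 4 * np.pi * big ** 2) if big == r2 else (4 * np.pi * big ** 2, 0.0)
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    h1 = r1 - x1
    x2 = d - x1
    h2 = r2 - x2
    return (
        4 * np.pi * r1 ** 2 - 2 * np.pi * r1 * h1,
        4 * np.pi * r2 ** 2 - 2 * np.pi * r2 * h2,
    )
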