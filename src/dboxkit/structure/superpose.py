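"""Least-squares rigid superposition (Kabsch) and cross-model Ca RMSD."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .model import StructureModel


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid transform mapping coordinate set B onto A.

    ``rotation`` is proper orthogonal (det = +1); applying
    ``B @ rotation.T + translation`` gives the superposed copy of B.
    """

    rotation: np.ndarray   # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd: float            # Angstrom, after the transform
    n_atoms: int
    chain_mapping: tuple[tuple[str, str], ...] | None = None
    n_excluded: int = 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(coordsA: np.ndarray, coordsB: np.ndarray) -> Superposition:
    """Optimal rigid superposition of B onto A by SVD of the covariance.

    A reflection is never returned: when the best orthogonal transform is
    improper, the smallest singular direction is flipped, yielding the
    optimal proper rotation. Degenerate inputs (fewer than 3 pairs, or
    collinear/coincident points) are rejected because the rotation is then
    underdetermined.
    """
    A = np.asarray(coordsA, dtype=float)
    B = np.asarray(coordsB, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"need equal-length (n,3) arrays, got {A.shape} and {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atom pairs")
    cA, cB = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - cA, B - cB
    # collinearity check: rank of the centred configuration
    if min(np.linalg.matrix_rank(A0, tol=1e-8), np.linalg.matrix_rank(B0, tol=1e-8)) < 2:
        raise ValueError("degenerate (collinear or coincident) coordinates")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cA - R @ cB
    diff = B0 @ R.T - A0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def _ca_map(model: StructureModel, chain_id: str) -> dict[tuple[int, str], np.ndarray]:
    out = {}
    for res in model.chain(chain_id).protein_residues():
        ca = res.atom("CA")
        if ca is not None:
            out[res.key] = ca.pos
    return out


def _chain_groups(model: StructureModel) -> dict[str, list[str]]:
    """Group protein chain ids by identical sequence."""
    groups: dict[str, list[str]] = {}
    for c in model.chains:
        seq = c.sequence()
        if seq:
            groups.setdefault(seq, []).append(c.id)
    return groups


def complex_ca_rmsd(modelA: StructureModel, modelB: StructureModel) -> Superposition:
    """All-Ca RMSD between two models of the same complex.

    Chains are paired by sequence identity; within each group of
    sequence-identical chains (e.g. the two protomers of a homodimer,
    whose labels may not correspond across crystal forms) every
    permutation is evaluated and the mapping with the lowest RMSD is
    returned. Residues are paired by author number and insertion code;
    residues missing a Ca in either model are excluded and counted.
    """
    groupsA, groupsB = _chain_groups(modelA), _chain_groups(modelB)
    shared = [s for s in groupsA if s in groupsB]
    if not shared:
        raise ValueError("models share no chains of identical sequence")
    # candidate mappings: cartesian product of per-group permutations
    per_group: list[list[list[tuple[str, str]]]] = []
    for seq in shared:
        a_ids, b_ids = groupsA[seq], groupsB[seq]
        k = min(len(a_ids), len(b_ids))
        opts = [
            list(zip(a_ids[:k], perm))
            for perm in permutations(b_ids, k)
        ]
        per_group.append(opts)

    def all_mappings(idx: int) -> list[list[tuple[str, str]]]:
        if idx == len(per_group):
            return [[]]
        return [
            opt + rest
            for opt in per_group[idx]
            for rest in all_mappings(idx + 1)
        ]

    best: Superposition | None = None
    for mapping in all_mappings(0):
        A_pts, B_pts, excluded = [], [], 0
        for a_id, b_id in mapping:
            mapA, mapB = _ca_map(modelA, a_id), _ca_map(modelB, b_id)
            common = sorted(set(mapA) & set(mapB))
            excluded += len(set(mapA) ^ set(mapB))
            A_pts += [mapA[k] for k in common]
            B_pts += [mapB[k] for k in common]
        if len(A_pts) < 3:
            continue
        sup = kabsch_superpose(np.array(A_pts), np.array(B_pts))
        sup = Superposition(
            sup.rotation, sup.translation, sup.rmsd, sup.n_atoms,
            chain_mapping=tuple(mapping), n_excluded=excluded,
        )
        if best is None or sup.rmsd < best.rmsd:
            best = sup
    if best is None:
        raise ValueError("no common Ca atoms between the two models")
    return best
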