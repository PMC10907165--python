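"""Synthetic-data generators with embedded ground truth.

Every input class the pipeline consumes can be generated here: ITC
thermograms and anisotropy titrations at stated binding parameters,
TonB-like sequences with embedded D-box motifs, ideal two-strand beta
geometries with an analytically enumerated hydrogen-bond ladder, ideal
alpha helices, and cage fixtures for burial calculations. All generators
are deterministic under a fixed seed, use an isolated RNG stream per call,
and return a machine-readable truth record alongside the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .binding.isotherm import BindingTruth, ItcProtocol, itc_injection_heats, anisotropy_model
from .binding.models import TitrationSeries
from .motif import DBOX_PATTERN, DEFAULT_PHI_SET, scan_dbox
from .sequences import AnnotatedSequence, STANDARD_AA
from .structure.hbonds import detect_backbone_hbonds
from .structure.model import Atom, Chain, Residue, StructureModel

# ------------------------------------------------------------------ binding

#: Default ITC noise: 2% of the first injection's heat.
ITC_NOISE_FRACTION = 0.02
#: Default anisotropy noise (SD of a plate-reader replicate).
ANISOTROPY_NOISE_SD = 0.002


def gen_itc_series(truth: BindingTruth, protocol: ItcProtocol | None = None,
                   noise_sd: float | None = None, seed: int = 0
                   ) -> tuple[TitrationSeries, dict]:
    """Simulated single-site ITC thermogram with Gaussian injection noise.

    ``noise_sd`` defaults to 2% of the first model heat; the returned truth
    record carries the generating parameters and the realised noise level.
    """
    protocol = protocol or ItcProtocol()
    q = itc_injection_heats(truth, protocol)
    if noise_sd is None:
        noise_sd = ITC_NOISE_FRACTION * abs(q[0])
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    heats = q + rng.normal(0.0, noise_sd, size=q.size) if noise_sd > 0 else q.copy()
    series = TitrationSeries(
        "ITC", heats=tuple(float(h) for h in heats), protocol=protocol,
        meta={"truth": asdict(truth), "noise_sd": noise_sd, "seed": seed},
    )
    return series, dict(series.meta)


def default_anisotropy_grid(low: float = 0.5, high: float = 500.0) -> tuple[float, ...]:
    """Two-fold protein dilution series from ``high`` down to ~``low`` uM,
    returned ascending."""
    grid = []
    p = high
    while p >= low * 0.99:
        grid.append(p)
        p /= 2.0
    return tuple(sorted(grid))


def gen_anisotropy_series(truth: BindingTruth,
                          Pt_grid: Sequence[float] | None = None,
                          Lt: float = 0.1,
                          noise_sd: float = ANISOTROPY_NOISE_SD,
                          seed: int = 0) -> tuple[TitrationSeries, dict]:
    """Simulated anisotropy titration of a fixed labelled peptide (default
    100 nM = 0.1 uM) against a protein dilution series."""
    Pt = tuple(Pt_grid) if Pt_grid is not None else default_anisotropy_grid()
    A = np.asarray(
        anisotropy_model(np.asarray(Pt), Lt, truth.A0, truth.Amax, truth.Kd)
    )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        A = A + rng.normal(0.0, noise_sd, size=A.size)
    series = TitrationSeries(
        "ANISOTROPY", Pt=Pt, Lt=Lt, A=tuple(float(a) for a in A),
        meta={"truth": asdict(truth), "mode": "corrected",
              "noise_sd": noise_sd, "seed": seed},
    )
    return series, dict(series.meta)


# ------------------------------------------------------------------ motifs

PHI_LETTERS = "IVLMF"        # hydrophobic letters sampled for phi positions
ZETA_LETTERS = "STQNDEKR"    # hydrophilic letters sampled for zeta positions


def _sample_motif(rng: np.random.Generator) -> str:
    core = "".join(
        rng.choice(list(PHI_LETTERS if sym == "Φ" else ZETA_LETTERS))
        for sym in DBOX_PATTERN
    )
    return "P" + core + "P"


def gen_motif_sequences(n: int = 10, length: int = 120, n_motifs: int = 1,
                        background_composition: dict[str, float] | None = None,
                        seed: int = 0, max_retries: int = 100,
                        ) -> tuple[list[AnnotatedSequence], list[dict]]:
    """Random sequences with D-box motifs embedded at recorded positions.

    Motifs are embedded as P + (7-residue pattern core) + P at
    non-overlapping slots; the background is rejection-sampled until a
    proline-gated scan recovers exactly the embedded cores, so the truth
    table is exact by construction.
    """
    if length < 9 * n_motifs:
        raise ValueError(f"length {length} too short for {n_motifs} motifs")
    letters = sorted(background_composition) if background_composition else sorted(STANDARD_AA)
    probs = None
    if background_composition:
        w = np.array([background_composition[aa] for aa in letters], dtype=float)
        probs = w / w.sum()
    rng = np.random.default_rng(seed)
    seqs, truth = [], []
    for k in range(n):
        for attempt in range(max_retries):
            bg = "".join(rng.choice(letters, size=length, p=probs))
            slot = 9  # P + core + P
            starts = []
            if n_motifs:
                # partition the sequence into n_motifs stretches, one slot each
                stride = length // n_motifs
                if stride < slot:
                    raise ValueError("motifs would overlap")
                for m in range(n_motifs):
                    lo = m * stride
                    hi = (m + 1) * stride - slot
                    starts.append(int(rng.integers(lo, hi + 1)))
            chars = list(bg)
            cores = []
            for s in starts:
                motif = _sample_motif(rng)
                chars[s : s + slot] = motif
                cores.append((s + 1, motif[1:-1]))  # core begins after the P
            candidate = "".join(chars)
            seq = AnnotatedSequence(f"synth_{k:03d}", candidate)
            hits = scan_dbox(seq, propensity_threshold=None)
            expected = {(c[0] + 1, c[1]) for c in cores}  # author numbering, offset 1
            got = {(m.core_start, m.core_sequence) for m in hits}
            if got == expected:
                seqs.append(seq)
                for start_author, core in sorted(expected):
                    truth.append(
                        {
                            "seq_id": seq.id,
                            "core_start": start_author,
                            "core_end": start_author + 6,
                            "core_seq": core,
                        }
                    )
                break
        else:
            raise RuntimeError(
                f"could not draw a clean background for sequence {k} after "
                f"{max_retries} attempts"
            )
    return seqs, truth


# --------------------------------------------------------- ideal geometries

# Engh-Huber-style backbone parameters (Angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

STRAND_PHI_PSI = {"antiparallel": (-139.0, 135.0), "parallel": (-119.0, 113.0)}
HELIX_PHI_PSI = (-57.0, -47.0)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d from internal coordinates (natural extension reference
    frame); ``angle`` = angle(b,c,d), ``dihedral`` = dihedral(a,b,c,d), degrees."""
    theta, chi = math.radians(angle), math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(chi),
         math.sin(theta) * math.sin(chi)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(n_res: int, phi: float, psi: float, omega: float = 180.0
                   ) -> list[dict[str, np.ndarray]]:
    """Ideal-geometry backbone (N, CA, C, O per residue) at fixed phi/psi."""
    if n_res < 1:
        raise ValueError("need at least one residue")
    res: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    C = CA + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0]) * -1.0
    C = _nerf(np.array([0.0, 1.0, 0.0]), N, CA, _B_CA_C, _A_N_CA_C, 0.0)
    res.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n_res):
        p = res[-1]
        N1 = _nerf(p["N"], p["CA"], p["C"], _B_C_N, _A_CA_C_N, psi)
        CA1 = _nerf(p["CA"], p["C"], N1, _B_N_CA, _A_C_N_CA, omega)
        C1 = _nerf(p["C"], N1, CA1, _B_CA_C, _A_N_CA_C, phi)
        res.append({"N": N1, "CA": CA1, "C": C1})
    for i, r in enumerate(res):
        if i + 1 < len(res):
            # O opposite the next N across the peptide plane
            r["O"] = _nerf(res[i + 1]["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, 180.0)
        else:
            r["O"] = _nerf(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    return res


def _add_amide_hydrogens(residues: list[dict[str, np.ndarray]]) -> None:
    """Explicit amide H: the DSSP placement for i >= 1; the N-terminal H
    copies the direction of the same-parity residue two positions along."""
    for i in range(1, len(residues)):
        prev, cur = residues[i - 1], residues[i]
        v = prev["C"] - prev["O"]
        cur["H"] = cur["N"] + v / np.linalg.norm(v)
    if len(residues) >= 3:
        residues[0]["H"] = residues[0]["N"] + (
            residues[2]["H"] - residues[2]["N"]
        )


def _to_chain(residues: list[dict[str, np.ndarray]], chain_id: str,
              resname: str = "ALA", start: int = 1) -> Chain:
    out = []
    for i, r in enumerate(residues):
        atoms = [Atom(name, "H" if name == "H" else name[0], pos)
                 for name, pos in r.items()]
        out.append(Residue(number=start + i, icode="", name=resname, atoms=atoms))
    return Chain(chain_id, out)


def _transform(residues: list[dict[str, np.ndarray]], rotvec: np.ndarray,
               trans: np.ndarray) -> list[dict[str, np.ndarray]]:
    R = Rotation.from_rotvec(rotvec).as_matrix()
    return [{k: R @ v + trans for k, v in r.items()} for r in residues]


BondSpec = tuple[tuple[str, int], tuple[str, int]]  # (donor chain,res#) -> (acceptor chain,res#)


def _target_bonds(kind: str, n_res: int, register_offset: int = 0,
                  parity: int = 0) -> list[tuple[int, int, str]]:
    """(donor index, acceptor index, donor strand) triples, 0-based.

    Antiparallel: reciprocal bonds between narrow pairs (i, j = n-1-i+off).
    Parallel: the full periodic slanted ladder - B's engaged residues donate
    to A one position back and A's donate back to B one position back.
    ``parity`` (0 or 1) selects which face of strand A the ladder occupies
    (a strand's even- and odd-numbered peptide groups point to opposite
    sides), letting two independent ladders share one central strand.
    """
    bonds = []
    if kind == "antiparallel":
        for i in range(parity, n_res, 2):
            j = n_res - 1 - i + register_offset
            if 0 <= j < n_res:
                bonds.append((i, j, "A"))
                bonds.append((j, i, "B"))
    elif kind == "parallel":
        for i in range(1 + parity, n_res, 2):
            j = i + register_offset
            if 0 <= j < n_res:
                bonds.append((j, i - 1, "B"))
        for k in range(2 - parity, n_res, 2):
            j = k - 1 + register_offset
            if 0 <= j < n_res:
                bonds.append((k, j, "A"))
    else:
        raise ValueError(f"unsupported beta-pair type {kind!r}")
    if not bonds:
        raise ValueError("no feasible target bonds for these parameters")
    return bonds


def _expected_bridges(kind: str, n_res: int) -> list[tuple[int, int]]:
    if kind == "antiparallel":
        out = [(i, n_res - 1 - i) for i in range(0, n_res, 2)]
        out += [
            (i, n_res - 1 - i)
            for i in range(1, n_res - 1, 2)
            if n_res - 1 - i >= 1
        ]
        return sorted(out)
    # every interior residue pair bridges, alternating between the two
    # parallel clauses
    return [(i, i) for i in range(1, n_res - 1)]


_PAIR_CACHE: dict[tuple, tuple[StructureModel, list]] = {}


def gen_ideal_beta_pair(kind: Literal["parallel", "antiparallel"],
                        n_res: int = 5, register_offset: int = 0,
                        separation: float = 0.0,
                        ) -> tuple[StructureModel, list[BondSpec]]:
    """Two ideal poly-alanine strands with a canonical hydrogen-bond ladder.

    Strand A is fixed; strand B's rigid placement is solved (deterministic
    least squares over several initial placements) so that the requested
    ladder's N-H...O=C geometries hit textbook values (H...O 1.9 A,
    N...O 2.9 A). The expected bond list is enumerated analytically and the
    assembled model is verified against the Kabsch-Sander detector before
    being returned; ``separation`` > 0 pushes strand B away along the
    inter-strand axis (for producing bond-free controls).
    """
    if kind not in STRAND_PHI_PSI:
        raise ValueError(f"unsupported beta-pair type {kind!r}")
    if n_res < 3:
        raise ValueError("need at least 3 residues per strand")
    cache_key = ("pair", kind, n_res, register_offset, separation)
    if cache_key in _PAIR_CACHE:
        import copy

        model, expected = _PAIR_CACHE[cache_key]
        return copy.deepcopy(model), list(expected)
    phi, psi = STRAND_PHI_PSI[kind]
    strandA = build_backbone(n_res, phi, psi)
    strandB0 = build_backbone(n_res, phi, psi)
    _add_amide_hydrogens(strandA)
    _add_amide_hydrogens(strandB0)
    targets = _target_bonds(kind, n_res, register_offset)
    strandB, resid = _solve_placement(strandA, strandB0, targets, kind)
    if separation:
        axis, perp, mid = _strand_frame(strandA)
        shift = separation * perp * (1.0 if np.dot(
            strandB[n_res // 2]["CA"] - mid, perp) >= 0 else -1.0)
        strandB = [{k: v + shift for k, v in r.items()} for r in strandB]
    model = StructureModel(
        f"ideal_{kind}_{n_res}",
        [_to_chain(strandA, "A"), _to_chain(strandB, "B")],
    )
    expected: list[BondSpec] = [
        ((d_strand, d_idx + 1),
         ("B" if d_strand == "A" else "A", a_idx + 1))
        for d_idx, a_idx, d_strand in targets
    ]
    if not separation:
        if resid > 0.2:
            raise RuntimeError(
                f"ideal {kind} pair: placement failed to reach target "
                f"geometry (rms residual {resid:.3f} A)"
            )
        _verify_ladder(model, expected)
    _PAIR_CACHE[cache_key] = (model, expected)
    import copy

    return copy.deepcopy(model), list(expected)


def _strand_frame(strand: list[dict[str, np.ndarray]]):
    axis = strand[-1]["CA"] - strand[0]["CA"]
    axis /= np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    return axis, perp, strand[len(strand) // 2]["CA"]


def _solve_placement(strandA, strandB0, targets, kind: str,
                     side: float | None = None):
    """Rigidly place a partner strand so the target N-H...O=C geometries hit
    textbook values (H...O 1.9 A, N...O 2.9 A). Deterministic least squares
    from a small set of initial placements; ``side`` (+1/-1) restricts the
    inital offsets to one face of the fixed strand."""
    n_res = len(strandA)

    def residuals(x: np.ndarray) -> np.ndarray:
        B = _transform(strandB0, x[:3], x[3:])
        res = []
        for d_idx, a_idx, d_strand in targets:
            donor = (strandA if d_strand == "A" else B)[d_idx]
            accep = (B if d_strand == "A" else strandA)[a_idx]
            res.append(np.linalg.norm(donor["H"] - accep["O"]) - 1.9)
            res.append(np.linalg.norm(donor["N"] - accep["O"]) - 2.9)
        return np.array(res)

    axis, perp, mid = _strand_frame(strandA)
    center = strandB0[n_res // 2]["CA"]
    inits = []
    signs = (1.0, -1.0) if side is None else (float(side),)
    for sign in signs:
        anchor = mid + sign * 4.9 * perp
        if kind == "antiparallel":
            rot_axes = (axis, np.array([0.0, 0.0, 1.0]), perp)
        else:
            rot_axes = (None, axis)
        for rot_axis in rot_axes:
            if rot_axis is None:
                rv = np.zeros(3)
                t = anchor - center
            else:
                rv = math.pi * rot_axis / np.linalg.norm(rot_axis)
                t = anchor - Rotation.from_rotvec(rv).as_matrix() @ center
            inits.append(np.concatenate([rv, t]))
    best = None
    for x0 in inits:
        sol = least_squares(residuals, x0, method="trf", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
        if math.sqrt(best.cost / len(targets)) < 0.05:
            break  # this init already reaches textbook geometry
    placed = _transform(strandB0, best.x[:3], best.x[3:])
    rms = math.sqrt(2.0 * best.cost / (2 * len(targets)))
    return placed, rms


def _verify_ladder(model: StructureModel, expected: list[BondSpec]) -> None:
    detected = {
        ((b.donor.chain_id, b.donor.number),
         (b.acceptor.chain_id, b.acceptor.number))
        for b in detect_backbone_hbonds(model)
        if b.donor.chain_id != b.acceptor.chain_id
    }
    if detected != set(expected):
        raise RuntimeError(
            f"{model.name}: detected inter-chain bonds {sorted(detected)} "
            f"differ from expected {sorted(expected)}"
        )


def gen_recruitment_fixture(n_res: int = 7
                            ) -> tuple[StructureModel, list[BondSpec]]:
    """A peptide strand simultaneously recruited by two partner strands.

    Emulates the geometry of the TonB D-box in the ExbD dimer groove: the
    central peptide chain P donates one face to a parallel ladder with
    chain A and the other face to an antiparallel ladder with chain B. The
    expected inter-chain bond list is enumerated at generation and verified
    against the detector before the model is returned.
    """
    if n_res < 5:
        raise ValueError("need at least 5 peptide residues")
    cache_key = ("recruitment", n_res)
    if cache_key in _PAIR_CACHE:
        import copy

        model, expected = _PAIR_CACHE[cache_key]
        return copy.deepcopy(model), list(expected)
    phi, psi = STRAND_PHI_PSI["parallel"]
    peptide = build_backbone(n_res, phi, psi)
    partnerA0 = build_backbone(n_res, phi, psi)
    partnerB0 = build_backbone(n_res, phi, psi)
    for s in (peptide, partnerA0, partnerB0):
        _add_amide_hydrogens(s)
    targetsA = _target_bonds("parallel", n_res, parity=0)
    targetsB = _target_bonds("antiparallel", n_res, parity=1)
    placedA, residA = _solve_placement(peptide, partnerA0, targetsA,
                                       "parallel", side=+1.0)
    placedB, residB = _solve_placement(peptide, partnerB0, targetsB,
                                       "antiparallel", side=-1.0)
    if max(residA, residB) > 0.2:
        raise RuntimeError(
            f"recruitment fixture: placement residuals {residA:.3f}/"
            f"{residB:.3f} A exceed tolerance"
        )
    model = StructureModel(
        f"recruitment_{n_res}",
        [_to_chain(peptide, "P"), _to_chain(placedA, "A"),
         _to_chain(placedB, "B")],
    )

    def relabel(spec_chain: str, partner: str) -> str:
        return "P" if spec_chain == "A" else partner

    expected: list[BondSpec] = []
    for targets, partner in ((targetsA, "A"), (targetsB, "B")):
        for d_idx, a_idx, d_strand in targets:
            expected.append(
                ((relabel(d_strand, partner), d_idx + 1),
                 (relabel("B" if d_strand == "A" else "A", partner), a_idx + 1))
            )
    _verify_ladder(model, expected)
    _PAIR_CACHE[cache_key] = (model, expected)
    import copy

    return copy.deepcopy(model), list(expected)


def expected_bridge_pairs(kind: str, n_res: int) -> list[tuple[int, int]]:
    """Author-numbered (A-residue, B-residue) bridge pairs of the ideal
    fixture, enumerated from the ladder construction rules."""
    return [(i + 1, j + 1) for i, j in _expected_bridges(kind, n_res)]


def gen_ideal_helix(n_res: int = 12) -> StructureModel:
    """Single ideal alpha helix (phi = -57, psi = -47), poly-alanine."""
    residues = build_backbone(n_res, *HELIX_PHI_PSI)
    return StructureModel("ideal_helix", [_to_chain(residues, "A")])


# ----------------------------------------------------------- burial fixture

_VAL_SIDECHAIN = {
    "CB": np.array([-0.55, -0.77, -1.21]),
    "CG1": np.array([-1.80, -1.50, -0.72]),
    "CG2": np.array([0.57, -1.70, -1.70]),
}


def gen_burial_fixture(pocket_radius: float = 4.0, n_cage: int = 250,
                       coverage: float = 1.0) -> StructureModel:
    """A single valine-like residue whose side chain sits at the centre of a
    spherical cage of carbon atoms (a separate chain).

    The default radius keeps every surface sample point of the side chain
    within contact range of the cage: Shrake-Rupley counts the interior of
    a roomy closed cavity as accessible (it has no notion of connectivity
    to bulk solvent), so full burial requires a snug pocket, exactly as in
    a real protein core. ``coverage`` in (0, 1] keeps only that fraction of
    the cage (by polar angle), giving intermediate burial for monotonicity
    checks; 0 removes the cage entirely.
    """
    backbone = {
        "N": np.array([1.20, 1.30, 0.60]),
        "CA": np.array([0.00, 0.60, 0.20]),
        "C": np.array([-0.10, 0.75, 1.70]),
        "O": np.array([-1.05, 1.40, 2.20]),
    }
    atoms = [Atom(n, n[0], p) for n, p in backbone.items()]
    atoms += [Atom(n, "C", p) for n, p in _VAL_SIDECHAIN.items()]
    target = Chain("P", [Residue(1, "", "VAL", atoms)])
    chains = [target]
    if coverage > 0:
        centroid = np.mean(list(_VAL_SIDECHAIN.values()), axis=0)
        from .structure.sasa import fibonacci_sphere

        pts = fibonacci_sphere(n_cage)
        keep = pts[pts[:, 2] >= (1.0 - 2.0 * coverage)]
        cage_res = [
            Residue(i + 1, "", "CAG", [Atom("C", "C", centroid + pocket_radius * p)])
            for i, p in enumerate(keep)
        ]
        chains.append(Chain("X", cage_res))
    return StructureModel(f"burial_cage_{coverage:g}", chains)


# ------------------------------------------------------------------ sidecar

def write_truth(truth: dict | list, path: str | Path) -> None:
    """Write a generator's ground-truth record as JSON."""
    Path(path).write_text(json.dumps(truth, indent=2, default=float))
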