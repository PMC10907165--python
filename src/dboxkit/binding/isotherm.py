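"""Single-site binding isotherms for ITC and fluorescence anisotropy.

Both assays reduce to the same exact (ligand-depletion) equilibrium: for
total concentrations P_t and L_t and dissociation constant K_d, the complex
concentration is the smaller root of the binding quadratic,

    C = [(K_d + L_t + P_t) - sqrt((K_d + L_t + P_t)^2 - 4 P_t L_t)] / 2 .

ITC observes the heat released as the complex concentration changes after
each injection; anisotropy observes the bound fraction of a fixed labelled
peptide as C / L_t. All concentrations are in uM, volumes in uL, enthalpies
in kcal/mol, heats in ucal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

AnisotropyMode = Literal["corrected", "as_printed"]


def bound_complex(Pt, Lt, Kd):
    """Equilibrium complex concentration (uM) from the binding quadratic.

    Accepts scalars or arrays. Uses the numerically stable root form
    ``2*Pt*Lt / (S + sqrt(S^2 - 4*Pt*Lt))`` (S = Kd + Lt + Pt), which avoids
    catastrophic cancellation when ``4*Pt*Lt << S^2``. The result always
    lies in ``[0, min(Pt, Lt)]``.
    """
    Pt = np.asarray(Pt, dtype=float)
    Lt = np.asarray(Lt, dtype=float)
    if np.any(Pt < 0) or np.any(Lt < 0):
        raise ValueError("total concentrations must be non-negative")
    if not Kd > 0:
        raise ValueError(f"Kd must be positive, got {Kd}")
    S = Kd + Lt + Pt
    disc = np.sqrt(np.maximum(S * S - 4.0 * Pt * Lt, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(S + disc > 0, 2.0 * Pt * Lt / (S + disc), 0.0)
    c = np.minimum(c, np.minimum(Pt, Lt))
    return c if c.ndim else float(c)


def anisotropy_model(Pt, Lt: float, A0: float, Amax: float, Kd: float,
                     mode: AnisotropyMode = "corrected"):
    """Anisotropy of a fixed labelled peptide titrated with protein.

    ``corrected`` (default): A = A0 + (Amax - A0) * C / Lt, the bound
    fraction of the labelled species; monotone in Pt and saturating at Amax.
    ``as_printed``: divides the quadratic's numerator by 2*Pt instead of
    2*Lt, reproducing the expression as some instrument-software templates
    print it; at Pt = 0 the limit of the bound term is 0 and A0 is returned.
    """
    Pt = np.asarray(Pt, dtype=float)
    C = np.asarray(bound_complex(Pt, Lt, Kd))
    if mode == "corrected":
        frac = C / Lt
    elif mode == "as_printed":
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(Pt > 0, C / Pt, 0.0)
    else:
        raise ValueError(f"unknown anisotropy mode {mode!r}")
    A = A0 + (Amax - A0) * frac
    return A if A.ndim else float(A)


@dataclass(frozen=True)
class ItcProtocol:
    """Injection protocol of a displacement (overflow) calorimeter cell.

    The macromolecule (here the ExbD periplasmic-domain monomer) sits in the
    cell; the injectant (D-box peptide) is in the syringe.
    """

    cell_volume: float = 200.0            # uL
    cell_concentration: float = 100.0     # uM macromolecule
    syringe_concentration: float = 1000.0  # uM injectant
    injection_volumes: tuple[float, ...] = (2.0,) * 20  # uL each
    temperature: float = 288.0            # K

    def __post_init__(self) -> None:
        if min(self.cell_volume, self.cell_concentration,
               self.syringe_concentration) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if len(self.injection_volumes) < 2:
            raise ValueError("need at least 2 injections")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")


@dataclass(frozen=True)
class BindingTruth:
    """Ground-truth (or initial-guess) binding parameters.

    ``n`` is injectant binding sites per macromolecule monomer; the 2:1
    ExbD:D-box stoichiometry corresponds to n = 0.5. ``dH`` applies to ITC,
    ``A0``/``Amax`` to anisotropy.
    """

    Kd: float            # uM
    n: float = 1.0       # sites per macromolecule
    dH: float = -8.0     # kcal/mol of injectant bound
    A0: float = 0.05
    Amax: float = 0.20

    def __post_init__(self) -> None:
        if not self.Kd > 0:
            raise ValueError("Kd must be positive")
        if self.Amax < self.A0:
            raise ValueError("Amax must be >= A0")


def itc_concentrations(protocol: ItcProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Total macromolecule and injectant concentrations in the cell after
    each injection, under the overflow-cell convention.

    Each injection of volume dV displaces an equal volume of well-mixed,
    pre-injection cell contents, so existing totals are diluted by
    (1 - dV/V0) before the injected material is added.
    """
    V0 = protocol.cell_volume
    M = protocol.cell_concentration
    X = 0.0
    Ms, Xs = [], []
    for dV in protocol.injection_volumes:
        if dV >= V0:
            raise ValueError("injection volume must be smaller than the cell")
        f = 1.0 - dV / V0
        M *= f
        X = X * f + protocol.syringe_concentration * dV / V0
        Ms.append(M)
        Xs.append(X)
    return np.array(Ms), np.array(Xs)


def itc_injection_heats(truth: BindingTruth, protocol: ItcProtocol) -> np.ndarray:
    """Per-injection heats (ucal) of a single-site titration.

    After injection i the cell holds macromolecule total M_i and injectant
    total X_i; the complex concentration C_i follows the binding quadratic
    with site total n*M_i. The measured heat is

        q_i = V0 * dH * (C_i - C_{i-1} * (1 - dV_i/V0)) * 1e-3

    (the displaced volume carries away complex formed earlier; the 1e-3
    converts uL * uM * kcal/mol to ucal). Heats tend to zero as the cell
    saturates.
    """
    V0 = protocol.cell_volume
    Ms, Xs = itc_concentrations(protocol)
    C = bound_complex(Pt=truth.n * Ms, Lt=Xs, Kd=truth.Kd)
    q = np.empty(len(Ms))
    C_prev = 0.0
    for i, dV in enumerate(protocol.injection_volumes):
        dC = C[i] - C_prev * (1.0 - dV / V0)
        q[i] = V0 * truth.dH * dC * 1e-3
        C_prev = C[i]
    return q


def equilibrium_heats_oracle(truth: BindingTruth, protocol: ItcProtocol) -> np.ndarray:
    """Brute-force mass-balance oracle for the ITC heats.

    Tracks absolute amounts (pmol) rather than concentrations and re-solves
    the equilibrium from scratch after every injection by bisection on the
    free-site concentration, without reusing the quadratic path above.
    Intended for tests.
    """
    V0 = protocol.cell_volume
    n_M = V0 * protocol.cell_concentration * truth.n  # site amount, uL*uM = pmol
    n_X = 0.0
    q = []
    C_prev_conc = 0.0
    for dV in protocol.injection_volumes:
        f = 1.0 - dV / V0
        n_M *= f
        n_X = n_X * f + protocol.syringe_concentration * dV
        St, Xt = n_M / V0, n_X / V0  # totals, uM
        # solve C from C = St*Xt ... via bisection on C in [0, min(St,Xt)]
        lo, hi = 0.0, min(St, Xt)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            # f(C) = (St-C)(Xt-C) - Kd*C : positive when C too small
            if (St - mid) * (Xt - mid) - truth.Kd * mid > 0:
                lo = mid
            else:
                hi = mid
        C = 0.5 * (lo + hi)
        q.append(V0 * truth.dH * (C - C_prev_conc * f) * 1e-3)
        C_prev_conc = C
    return np.array(q)
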