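"""D-box motif discovery: hydropathy classes, beta-strand propensity, scanning.

The D-box is a seven-residue motif in the periplasmic linker of TonB with
hydropathy pattern phi-zeta-phi-zeta-phi-phi-zeta (hydrophobic/hydrophilic
alternation broken at position 6), typically flanked by prolines, that is
captured as a beta strand by a dimer of ExbD periplasmic domains. This
module classifies residues into the phi/zeta/P alphabet, computes
Chou-Fasman-style beta-strand propensity profiles, and scans sequences for
pattern matches with optional proline-flanking and propensity gates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequences import AnnotatedSequence, STANDARD_AA, iter_windows

PHI = "Φ"   # hydrophobic
ZETA = "ζ"  # hydrophilic
PRO = "P"        # proline, its own flanking class

#: Hydrophobic residue set. G and H are assigned zeta (neither occurs at a
#: phi position in any known D-box); override via the ``phi_set`` argument.
DEFAULT_PHI_SET = frozenset("ACFILMVWY")

#: The D-box core hydropathy pattern.
DBOX_PATTERN = PHI + ZETA + PHI + ZETA + PHI + PHI + ZETA
DBOX_CORE_LEN = 7

#: Chou-Fasman beta-sheet conformational propensities P(beta), normalised so
#: 1.0 is the average residue; values above ~1 favour strand.
CHOU_FASMAN_BETA: Mapping[str, float] = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
}


def classify_hydropathy(residue: str, phi_set: frozenset[str] = DEFAULT_PHI_SET) -> str:
    """Map a one-letter residue code to its hydropathy class.

    Proline maps to its own class ``P``; members of ``phi_set`` map to phi;
    every other standard residue (and ``X``) maps to zeta.
    """
    if not isinstance(residue, str) or len(residue) != 1:
        raise ValueError(f"expected a one-letter residue code, got {residue!r}")
    if residue == "P":
        return PRO
    if residue in phi_set:
        return PHI
    if residue in STANDARD_AA or residue == "X":
        return ZETA
    raise ValueError(f"unknown residue code {residue!r}")


def hydropathy_string(
    seq: AnnotatedSequence | str, phi_set: frozenset[str] = DEFAULT_PHI_SET
) -> str:
    """Classify every residue of a sequence; length-preserving."""
    residues = seq.residues if isinstance(seq, AnnotatedSequence) else seq
    out = []
    for i, aa in enumerate(residues):
        try:
            out.append(classify_hydropathy(aa, phi_set))
        except ValueError as exc:
            raise ValueError(f"position {i}: {exc}") from exc
    return "".join(out)


@dataclass(frozen=True)
class PropensityProfile:
    """Windowed beta-strand propensity profile of one sequence."""

    seq_id: str
    scores: tuple[float, ...]
    truncated: tuple[bool, ...]  # True where the window did not fully fit
    window: int
    threshold: float

    def __len__(self) -> int:
        return len(self.scores)


def beta_propensity_profile(
    seq: AnnotatedSequence,
    window: int = 5,
    table: Mapping[str, float] = CHOU_FASMAN_BETA,
    threshold: float = 1.0,
) -> PropensityProfile:
    """Sliding-window mean beta-strand propensity.

    Score at position ``i`` is the mean table value over the ``window``
    residues centred at ``i``; at the sequence ends the window shrinks to
    the available context and the position is flagged as truncated.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    missing = {aa for aa in STANDARD_AA if aa not in table}
    if missing:
        raise ValueError(f"propensity table missing residues: {sorted(missing)}")
    vals = [table.get(aa, 1.0) for aa in seq.residues]  # X scores neutral
    scores, trunc = [], []
    for lo, hi, t in iter_windows(len(vals), window):
        scores.append(sum(vals[lo:hi]) / (hi - lo))
        trunc.append(t)
    return PropensityProfile(seq.id, tuple(scores), tuple(trunc), window, threshold)


@dataclass(frozen=True)
class MotifMatch:
    """A located D-box candidate, reported in author numbering (inclusive)."""

    seq_id: str
    core_start: int
    core_end: int
    core_sequence: str
    upstream_proline: int | None
    downstream_proline: int | None
    mean_core_propensity: float
    passes_propensity: bool

    def __post_init__(self) -> None:
        if self.core_end - self.core_start != DBOX_CORE_LEN - 1:
            raise ValueError("D-box core must span exactly 7 residues")
        if len(self.core_sequence) != DBOX_CORE_LEN:
            raise ValueError("core_sequence must have 7 residues")


def _nearest_proline(residues: str, positions: Sequence[int]) -> int | None:
    for j in positions:
        if 0 <= j < len(residues) and residues[j] == "P":
            return j
    return None


def scan_dbox(
    seq: AnnotatedSequence,
    proline_window: int = 2,
    propensity_threshold: float | None = 1.0,
    require_prolines: bool = True,
    phi_set: frozenset[str] = DEFAULT_PHI_SET,
    propensity_window: int = 5,
    table: Mapping[str, float] = CHOU_FASMAN_BETA,
) -> list[MotifMatch]:
    """Scan a sequence for D-box motifs.

    A candidate is any 7-mer whose hydropathy string equals the D-box
    pattern. When ``require_prolines`` is set, a proline must occur within
    ``proline_window`` residues outside each end of the core. When
    ``propensity_threshold`` is not None, matches additionally carry a
    ``passes_propensity`` flag (mean windowed core propensity >= threshold)
    and matches failing the gate are dropped.

    Matches are returned in ascending position; overlapping matches are all
    reported. Coordinates are author-numbered and inclusive.
    """
    if len(seq) < DBOX_CORE_LEN:
        raise ValueError(
            f"sequence {seq.id!r} shorter than the 7-residue D-box core"
        )
    hstr = hydropathy_string(seq, phi_set)
    profile = beta_propensity_profile(
        seq, window=propensity_window, table=table,
        threshold=propensity_threshold if propensity_threshold is not None else 1.0,
    )
    matches: list[MotifMatch] = []
    for i in range(len(seq) - DBOX_CORE_LEN + 1):
        if hstr[i : i + DBOX_CORE_LEN] != DBOX_PATTERN:
            continue
        up = _nearest_proline(seq.residues, range(i - 1, i - 1 - proline_window, -1))
        down = _nearest_proline(
            seq.residues, range(i + DBOX_CORE_LEN, i + DBOX_CORE_LEN + proline_window)
        )
        if require_prolines and (up is None or down is None):
            continue
        mean_prop = sum(profile.scores[i : i + DBOX_CORE_LEN]) / DBOX_CORE_LEN
        passes = (
            propensity_threshold is None or mean_prop >= propensity_threshold
        )
        if propensity_threshold is not None and not passes:
            continue
        off = seq.numbering_offset
        matches.append(
            MotifMatch(
                seq_id=seq.id,
                core_start=off + i,
                core_end=off + i + DBOX_CORE_LEN - 1,
                core_sequence=seq.residues[i : i + DBOX_CORE_LEN],
                upstream_proline=None if up is None else off + up,
                downstream_proline=None if down is None else off + down,
                mean_core_propensity=mean_prop,
                passes_propensity=passes,
            )
        )
    return matches


def score_motif(
    match: MotifMatch,
    profile: PropensityProfile,
    anchor_end: int | None = None,
    distance_scale: float = 50.0,
) -> float:
    """Composite score for ranking D-box candidates.

    The score is the match's mean core propensity, multiplied (when
    ``anchor_end``, the author-numbered C-terminal residue of the membrane
    anchor, is given) by an exponential penalty in the distance between the
    anchor and the core start. A biologically plausible D-box sits
    immediately downstream of the anchor, so nearer matches rank higher.
    """
    if match.seq_id != profile.seq_id:
        raise ValueError(
            f"match is on sequence {match.seq_id!r} but profile is for "
            f"{profile.seq_id!r}"
        )
    score = match.mean_core_propensity
    if anchor_end is not None:
        import math

        dist = abs(match.core_start - anchor_end)
        score *= math.exp(-dist / distance_scale)
    return score


# ---------------------------------------------------------------- reporting

REPORT_COLUMNS = [
    "seq_id", "core_start", "core_end", "core_seq",
    "proline_up", "proline_down", "mean_propensity", "score",
]


def matches_to_frame(
    matches: Iterable[MotifMatch],
    profiles: Mapping[str, PropensityProfile] | None = None,
    anchor_end: int | None = None,
) -> pd.DataFrame:
    """Tabulate matches for TSV/JSON reporting."""
    rows = []
    for m in matches:
        score = (
            score_motif(m, profiles[m.seq_id], anchor_end)
            if profiles and m.seq_id in profiles
            else m.mean_core_propensity
        )
        rows.append(
            {
                "seq_id": m.seq_id,
                "core_start": m.core_start,
                "core_end": m.core_end,
                "core_seq": m.core_sequence,
                "proline_up": m.upstream_proline,
                "proline_down": m.downstream_proline,
                "mean_propensity": round(m.mean_core_propensity, 4),
                "score": round(score, 4),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(frame: pd.DataFrame, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write a motif report as ``<prefix>.tsv`` and ``<prefix>.json``."""
    out_prefix = Path(out_prefix)
    tsv, js = out_prefix.with_suffix(".tsv"), out_prefix.with_suffix(".json")
    frame.to_csv(tsv, sep="\t", index=False)
    js.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    return tsv, js
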