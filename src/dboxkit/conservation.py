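"""Pairwise global alignment, percent identity, conservation classes, and
mapping of conservation onto structure residues.

Multiple-alignment conservation is approximated by a star alignment: each
ortholog is aligned pairwise (Needleman-Wunsch, affine gaps, BLOSUM62) to a
common reference, and per-reference-column classes are assigned with the
Clustal strong/weak amino-acid groups, the vocabulary used when colouring
residue conservation on structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .sequences import AnnotatedSequence
from .structure.model import StructureModel

ConservationClass = Literal["identical", "strong", "weak", "none"]

#: Clustal "strong" groups (score > 0.5 in the Gonnet PAM250 series).
STRONG_GROUPS = [
    "STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW",
]
#: Clustal "weak" groups (score <= 0.5).
WEAK_GROUPS = [
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK", "NDEQHK",
    "NEQHRK", "FVLIM", "HFY",
]

IdentityDenominator = Literal["gapless", "alignment", "shorter"]


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both >= 0)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    def load_matrix(self):
        return substitution_matrices.load(self.matrix_name)


@dataclass(frozen=True)
class AlignmentResult:
    idA: str
    idB: str
    alignedA: str   # gapped, equal length
    alignedB: str
    score: float

    def __post_init__(self) -> None:
        if len(self.alignedA) != len(self.alignedB):
            raise ValueError("gapped sequences must have equal length")

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.alignedA, self.alignedB)


def global_align(seqA: AnnotatedSequence, seqB: AnnotatedSequence,
                 scheme: ScoringScheme = ScoringScheme()) -> AlignmentResult:
    """Optimal global alignment under affine gaps (Needleman-Wunsch).

    Deterministic: of the co-optimal alignments the aligner's first
    (diagonal-preferring) traceback is returned.
    """
    if not seqA.residues or not seqB.residues:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.load_matrix()
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    aln = aligner.align(seqA.residues, seqB.residues)[0]
    a, b = str(aln[0]), str(aln[1])
    # recompute the score of the returned alignment as a self-check
    assert abs(_score_alignment(a, b, scheme) - aln.score) < 1e-6
    return AlignmentResult(seqA.id, seqB.id, a, b, float(aln.score))


def _score_alignment(a: str, b: str, scheme: ScoringScheme) -> float:
    """Score a gapped alignment directly (also the test oracle's scorer)."""
    m = scheme.load_matrix()
    score, in_gap_a, in_gap_b = 0.0, False, False
    for ca, cb in zip(a, b):
        if ca == "-" and cb == "-":
            raise ValueError("double-gap column")
        if ca == "-":
            # a gap of length L costs open + (L-1)*extend
            score -= scheme.gap_extend if in_gap_a else scheme.gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= scheme.gap_extend if in_gap_b else scheme.gap_open
            in_gap_a, in_gap_b = False, True
        else:
            score += m[ca, cb]
            in_gap_a = in_gap_b = False
    return score


def percent_identity(aln: AlignmentResult,
                     denominator: IdentityDenominator = "gapless") -> float:
    """Percent identity of a pairwise alignment.

    The default denominator counts gapless columns (positions aligned in
    both sequences); ``alignment`` uses the full alignment length and
    ``shorter`` the length of the shorter ungapped sequence.
    """
    identical = sum(1 for ca, cb in aln.columns() if ca == cb and ca != "-")
    gapless = sum(1 for ca, cb in aln.columns() if ca != "-" and cb != "-")
    if denominator == "gapless":
        denom = gapless
    elif denominator == "alignment":
        denom = len(aln.alignedA)
    elif denominator == "shorter":
        denom = min(
            len(aln.alignedA.replace("-", "")), len(aln.alignedB.replace("-", ""))
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("alignment has no aligned columns; identity undefined")
    return 100.0 * identical / denom


def classify_column(residues: Sequence[str]) -> ConservationClass:
    """Conservation class of one alignment column (gaps break conservation)."""
    rs = set(residues)
    if "-" in rs or not rs:
        return "none"
    if len(rs) == 1:
        return "identical"
    for group in STRONG_GROUPS:
        if rs <= set(group):
            return "strong"
    for group in WEAK_GROUPS:
        if rs <= set(group):
            return "weak"
    return "none"


def column_classes(reference: AnnotatedSequence,
                   alignments: Sequence[AlignmentResult]) -> list[ConservationClass]:
    """Star-alignment conservation classes per reference residue.

    Every alignment must have the reference as its first sequence; each
    reference position collects the residues aligned to it across all
    alignments (a deletion contributes a gap, which forces class "none").
    """
    for aln in alignments:
        if aln.idA != reference.id or aln.alignedA.replace("-", "") != reference.residues:
            raise ValueError(
                f"alignment {aln.idA!r} vs {aln.idB!r} is not anchored on "
                f"reference {reference.id!r}"
            )
    per_pos: list[list[str]] = [[aa] for aa in reference.residues]
    for aln in alignments:
        ref_i = 0
        for ca, cb in aln.columns():
            if ca != "-":
                per_pos[ref_i].append(cb)
                ref_i += 1
    return [classify_column(col) for col in per_pos]


def identity_table(reference: AnnotatedSequence,
                   others: Sequence[AnnotatedSequence],
                   scheme: ScoringScheme = ScoringScheme(),
                   denominator: IdentityDenominator = "gapless",
                   ) -> tuple[pd.DataFrame, list[AlignmentResult]]:
    """Align every sequence to the reference; tabulate percent identities."""
    alns = [global_align(reference, s, scheme) for s in others]
    frame = pd.DataFrame(
        {
            "seq_id": [a.idB for a in alns],
            "percent_identity": [round(percent_identity(a, denominator), 2) for a in alns],
            "score": [a.score for a in alns],
        }
    )
    return frame, alns


def map_conservation(classes: Sequence[ConservationClass],
                     model: StructureModel, chain_id: str,
                     numbering_offset: int = 1,
                     mismatch_tolerance: float = 0.2) -> pd.DataFrame:
    """Map per-residue conservation classes onto a structure chain.

    Sequence position ``i`` (0-based) corresponds to author residue
    ``numbering_offset + i``. Structure residues outside the classified
    range are annotated "unaligned"; if more than ``mismatch_tolerance`` of
    the chain is unaligned a systematic numbering mismatch is assumed and
    an error raised.
    """
    chain = model.chain(chain_id)
    rows, unmatched = [], 0
    residues = chain.protein_residues()
    for res in residues:
        idx = res.number - numbering_offset
        if 0 <= idx < len(classes):
            cls = classes[idx]
        else:
            cls, unmatched = "unaligned", unmatched + 1
        rows.append({"chain": chain_id, "residue": res.number, "class": cls})
    if residues and unmatched / len(residues) > mismatch_tolerance:
        raise ValueError(
            f"{unmatched}/{len(residues)} residues of chain {chain_id!r} fall "
            f"outside the classified sequence: numbering offset "
            f"{numbering_offset} looks systematically wrong"
        )
    return pd.DataFrame(rows, columns=["chain", "residue", "class"])


def write_aligned_fasta(alns: Sequence[AlignmentResult], path: str | Path) -> None:
    lines = []
    for aln in alns:
        lines += [f">{aln.idA}", aln.alignedA, f">{aln.idB}", aln.alignedB]
    Path(path).write_text("\n".join(lines) + "\n")
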