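"""Annotated protein sequences and FASTA input/output.

Sequences carry an author-style numbering offset so that positions can be
reported in the numbering a structural biologist uses (e.g. the TonB D-box
peptide spans author residues 43-54 even though it is only 12 residues
long). Internally everything is 0-based and half-open; the offset is applied
only at the reporting boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
VALID_AA = STANDARD_AA | {"X"}

#: ``>id/start-end`` header convention used to carry author numbering in FASTA.
_RANGE_HEADER = re.compile(r"^(?P<id>.+)/(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class AnnotatedSequence:
    """A protein sequence with an identifier and author-numbering offset.

    Parameters
    ----------
    id : str
        Sequence identifier.
    residues : str
        One-letter amino-acid codes (the 20 standard codes plus ``X``).
    numbering_offset : int, default 1
        Author number of the first residue; author number of residue ``i``
        (0-based) is ``numbering_offset + i``.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        bad = [
            (i, aa)
            for i, aa in enumerate(self.residues)
            if aa not in VALID_AA
        ]
        if bad:
            i, aa = bad[0]
            raise ValueError(
                f"sequence {self.id!r}: invalid residue code {aa!r} at "
                f"position {i} (author residue {self.numbering_offset + i})"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def author_number(self, index: int) -> int:
        """Author residue number of 0-based position ``index``."""
        if not 0 <= index < len(self.residues):
            raise IndexError(f"position {index} outside sequence of length {len(self)}")
        return self.numbering_offset + index

    def index_of(self, author_number: int) -> int:
        """0-based position of an author residue number."""
        idx = author_number - self.numbering_offset
        if not 0 <= idx < len(self.residues):
            raise IndexError(
                f"author residue {author_number} outside range "
                f"{self.numbering_offset}-{self.numbering_offset + len(self) - 1}"
            )
        return idx


def read_fasta(path: str | Path, default_offset: int = 1) -> list[AnnotatedSequence]:
    """Read a multi-record FASTA file.

    A header of the form ``>name/43-54`` sets ``numbering_offset`` to 43
    (and the stated span is checked against the sequence length); otherwise
    ``default_offset`` applies.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        m = _RANGE_HEADER.match(rec.id)
        if m:
            start, end = int(m.group("start")), int(m.group("end"))
            if end - start + 1 != len(seq):
                raise ValueError(
                    f"record {rec.id!r}: stated range {start}-{end} does not "
                    f"match sequence length {len(seq)}"
                )
            out.append(AnnotatedSequence(m.group("id"), seq, start))
        else:
            out.append(AnnotatedSequence(rec.id, seq, default_offset))
    return out


def write_fasta(seqs: Iterable[AnnotatedSequence], path: str | Path) -> None:
    """Write sequences with the ``id/start-end`` header convention."""
    records = []
    for s in seqs:
        name = f"{s.id}/{s.numbering_offset}-{s.numbering_offset + len(s) - 1}"
        records.append(SeqRecord(Seq(s.residues), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def iter_windows(n: int, window: int) -> Iterator[tuple[int, int, bool]]:
    """Yield ``(lo, hi, truncated)`` half-open windows centred on 0..n-1.

    Windows are shrunk at the ends; ``truncated`` flags positions whose
    window could not be fully placed.
    """
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        yield lo, hi, (hi - lo) < window
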