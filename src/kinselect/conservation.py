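"""Residue conservation at reference-mapped alignment columns.

Given a multiple sequence alignment and one of its sequences designated
as the reference (e.g. a kinase catalytic subunit whose literature
numbering is used), this module answers questions of the form "what
fraction of the aligned sequences carry residue V at reference position
66?" — the computation behind claims that a binding-site residue is rare
across a kinome.

Conventions: reference positions are 1-based over the *ungapped*
reference sequence; residue matching is case-insensitive; gap characters
('-' and '.') count in the denominator but never match a residue query
(a sequence lacking the position does not "have" the residue); 'X' never
matches.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "AlignmentColumnProfile",
    "read_alignment",
    "map_reference_position",
    "residue_frequency",
    "column_profile",
    "GAP_CHARS",
]

GAP_CHARS = frozenset("-.")

_FORMATS = {"fasta": "fasta", "clustal": "clustal"}
_EXTENSION_FORMATS = {
    ".fa": "fasta", ".fasta": "fasta", ".afa": "fasta", ".aln": "clustal",
    ".clustal": "clustal", ".clw": "clustal",
}


@dataclass(frozen=True)
class AlignmentColumnProfile:
    """Residue composition of one alignment column, in reference coordinates."""

    reference_id: str
    reference_position: int  # 1-based, ungapped reference numbering
    alignment_column: int  # 0-based column index
    residue_counts: Mapping[str, int]  # uppercase residue (or gap char) -> count
    frequency_of: Mapping[str, float]  # queried residue -> fraction of sequences
    n_sequences: int

    def to_dict(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "reference_position": self.reference_position,
            "alignment_column": self.alignment_column,
            "n_sequences": self.n_sequences,
            "residue_counts": dict(self.residue_counts),
            "frequency_of": dict(self.frequency_of),
        }


def read_alignment(path: str | Path, format: str | None = None) -> MultipleSeqAlignment:
    """Read a FASTA or Clustal alignment; gaps preserved, lengths must agree.

    When *format* is omitted it is guessed from the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = _EXTENSION_FORMATS.get(path.suffix.lower())
        if format is None:
            raise ValueError(
                f"cannot guess alignment format from {path.suffix!r}; "
                "pass format='fasta' or 'clustal'"
            )
    if format not in _FORMATS:
        raise ValueError(f"unknown alignment format {format!r}; use fasta or clustal")
    alignment = AlignIO.read(str(path), _FORMATS[format])
    if len(alignment) < 2:
        raise ValueError("alignment must contain at least 2 sequences")
    return alignment


def _reference_record(alignment: MultipleSeqAlignment, reference_id: str):
    for record in alignment:
        if record.id == reference_id:
            return record
    raise KeyError(f"reference sequence {reference_id!r} not in alignment")


def map_reference_position(
    alignment: MultipleSeqAlignment, reference_id: str, position: int
) -> int:
    """0-based alignment column of the *position*-th non-gap reference residue.

    Strictly monotone in *position* and invertible over non-gap positions.
    """
    record = _reference_record(alignment, reference_id)
    if position < 1:
        raise ValueError(f"reference positions are 1-based (got {position})")
    seen = 0
    for column, char in enumerate(str(record.seq)):
        if char not in GAP_CHARS:
            seen += 1
            if seen == position:
                return column
    raise ValueError(
        f"position {position} beyond ungapped length {seen} of {reference_id!r}"
    )


def column_profile(
    alignment: MultipleSeqAlignment, column: int
) -> Counter:
    """Uppercase residue (and gap) counts of one alignment column."""
    if not (0 <= column < alignment.get_alignment_length()):
        raise IndexError(f"column {column} out of range")
    return Counter(
        char if char in GAP_CHARS else char.upper()
        for char in alignment[:, column]
    )


def residue_frequency(
    alignment: MultipleSeqAlignment,
    reference_id: str,
    position: int,
    residue: str,
) -> AlignmentColumnProfile:
    """Fraction of sequences carrying *residue* at a reference-numbered position.

    Gapped sequences count in the denominator, never as matches.
    """
    residue = residue.strip().upper()
    if len(residue) != 1 or not residue.isalpha():
        raise ValueError(f"residue must be a single letter, got {residue!r}")
    column = map_reference_position(alignment, reference_id, position)
    counts = column_profile(alignment, column)
    n = len(alignment)
    matches = 0 if residue == "X" else counts.get(residue, 0)
    return AlignmentColumnProfile(
        reference_id=reference_id,
        reference_position=position,
        alignment_column=column,
        residue_counts=dict(counts),
        frequency_of={residue: matches / n},
        n_sequences=n,
    )
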