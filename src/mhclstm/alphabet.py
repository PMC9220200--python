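"""Canonical amino-acid alphabet used throughout the package.

Every matrix whose rows or columns are indexed by amino acid (one-hot
encodings, substitution matrices, learned kernel banks, position-frequency
matrices) uses the alphabetical one-letter ordering below.  Fixing one
ordering project-wide keeps all of these objects directly comparable.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 canonical amino acids, alphabetical one-letter ordering."""

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_AMINO_ACIDS: int = 20


class InvalidResidueError(ValueError):
    """A peptide contains a letter outside the 20 canonical amino acids."""

    def __init__(self, sequence: str, position: int):
        self.sequence = sequence
        self.position = position  # 1-based
        super().__init__(
            f"invalid residue {sequence[position - 1]!r} at position "
            f"{position} of {sequence!r}"
        )


def validate_sequence(sequence: str) -> None:
    """Raise :class:`InvalidResidueError` at the first non-canonical letter."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    for pos, letter in enumerate(sequence, start=1):
        if letter not in AA_INDEX:
            raise InvalidResidueError(sequence, pos)


def is_canonical(sequence: str) -> bool:
    return bool(sequence) and all(c in AA_INDEX for c in sequence)
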